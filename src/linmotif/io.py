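"""Sequence and table I/O: FASTA proteomes, interaction tables, site
annotations and ranked result tables.

Coordinates are 0-based half-open everywhere inside the package.  Site
tables must declare their convention in the header line: columns
``protein_id / start / end`` are read as 0-based half-open, columns
``protein_id / start_1based / end_1based`` as 1-based inclusive and
converted on input.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .motif import AA_SET


class SequenceIOError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """One protein: identifier plus residue string (uppercased)."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise SequenceIOError("empty sequence id")
        if not self.residues:
            raise SequenceIOError(f"empty sequence for id {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def sentinel_positions(self) -> list:
        """Indices of non-canonical residues (never match any motif)."""
        return [i for i, c in enumerate(self.residues) if c not in AA_SET]


@dataclass
class ProteomePartition:
    """Disjoint positives / negatives / background sets for one target."""

    target_id: str
    positives: list
    negatives: list
    background: list
    unresolved: list = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for rs in (self.positives, self.negatives, self.background) for r in rs]
        if len(ids) != len(set(ids)):
            raise SequenceIOError("partition sets are not disjoint by id")
        if len(self.positives) < 1:
            raise SequenceIOError(f"no positives for target {self.target_id!r}")

    @property
    def n(self) -> int:
        return len(self.positives)

    @property
    def p(self) -> int:
        return len(self.negatives)

    @property
    def b(self) -> int:
        return len(self.background)

    @property
    def total(self) -> int:
        return self.n + self.p + self.b


@dataclass(frozen=True)
class BindingSiteAnnotation:
    """Annotated binding interval on a protein, 0-based half-open."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise SequenceIOError(
                f"invalid site interval [{self.start}, {self.end}) on {self.protein_id}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read a FASTA file into SequenceRecords.

    Header token before the first whitespace becomes the id; sequences are
    uppercased; non-canonical letters are preserved (they act as sentinels
    during matching).  Duplicate ids and empty sequences are errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceIOError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise SequenceIOError(f"empty sequence for id {rec.id!r}")
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as wrapped FASTA (deterministic, round-trips read_fasta)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Interaction table -> partition
# ---------------------------------------------------------------------------

def read_interactions(path) -> list:
    """Read a TSV of (target_id, binder_id) pairs with a header line."""
    pairs = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != [
            "target_id",
            "binder_id",
        ]:
            raise SequenceIOError(
                "interactions TSV must start with header 'target_id\\tbinder_id'"
            )
        for row in reader:
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise SequenceIOError(f"malformed interaction row: {row!r}")
            pairs.append((row[0].strip(), row[1].strip()))
    return pairs


def build_partition(interactions, proteome, target: str) -> ProteomePartition:
    """Partition a proteome into positives / negatives / background.

    Positives: binders of the target.  Negatives: binders of any other
    target in the table, minus the positives (a protein binding both the
    target and another family member counts as positive).  Background: the
    remaining proteome.  Binder ids absent from the proteome are collected
    in ``unresolved`` and reported, not fatal.
    """
    targets = {t for t, _ in interactions}
    if target not in targets:
        raise SequenceIOError(f"target {target!r} absent from interaction table")
    by_id = {}
    for rec in proteome:
        if rec.id in by_id:
            raise SequenceIOError(f"duplicate proteome id {rec.id!r}")
        by_id[rec.id] = rec

    pos_ids, other_ids, unresolved = set(), set(), []
    for t, b in interactions:
        if b not in by_id:
            unresolved.append((t, b))
            continue
        if t == target:
            pos_ids.add(b)
        else:
            other_ids.add(b)
    neg_ids = other_ids - pos_ids
    if not pos_ids:
        raise SequenceIOError(f"zero resolvable positives for target {target!r}")

    positives = [by_id[i] for i in sorted(pos_ids)]
    negatives = [by_id[i] for i in sorted(neg_ids)]
    background = [by_id[i] for i in sorted(set(by_id) - pos_ids - neg_ids)]
    return ProteomePartition(
        target_id=target,
        positives=positives,
        negatives=negatives,
        background=background,
        unresolved=unresolved,
    )


# ---------------------------------------------------------------------------
# Binding-site tables
# ---------------------------------------------------------------------------

_SITE_HEADERS = {
    ("protein_id", "start", "end"): "zero_half_open",
    ("protein_id", "start_1based", "end_1based"): "one_inclusive",
}


def read_sites(path, proteome=None) -> list:
    """Read site annotations; the header declares the coordinate convention.

    When ``proteome`` is given, intervals are bounds-checked against the
    named protein's length (errors name the offending row).
    """
    lengths = {r.id: len(r) for r in proteome} if proteome is not None else None
    sites = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        key = tuple(h.strip().lower() for h in header[:3])
        if key not in _SITE_HEADERS:
            raise SequenceIOError(
                f"site TSV header {header!r} does not declare a known coordinate "
                "convention; use protein_id/start/end (0-based half-open) or "
                "protein_id/start_1based/end_1based (1-based inclusive)"
            )
        one_based = _SITE_HEADERS[key] == "one_inclusive"
        for ln, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            pid, s, e = row[0].strip(), int(row[1]), int(row[2])
            if one_based:
                s, e = s - 1, e
            if s < 0 or s >= e:
                raise SequenceIOError(f"row {ln}: invalid interval [{s}, {e}) for {pid}")
            if lengths is not None:
                if pid not in lengths:
                    raise SequenceIOError(f"row {ln}: unknown protein {pid!r}")
                if e > lengths[pid] or s < 0:
                    raise SequenceIOError(
                        f"row {ln}: site [{s}, {e}) outside protein {pid} "
                        f"(length {lengths[pid]})"
                    )
            sites.append(BindingSiteAnnotation(pid, s, e))
    return sites


# ---------------------------------------------------------------------------
# Ranked result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = (
    "motif",
    "length",
    "k_pos",
    "q_neg",
    "m_bak",
    "log10_pNEG",
    "log10_pBAK",
    "zNEG",
    "zBAK",
    "z",
)


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        if math.isinf(x):
            return "-inf" if x < 0 else "inf"
        return format(x, ".6g")
    return str(x)


def write_results(scored, path) -> None:
    """Write ranked ScoredMotifs as a TSV, deterministic formatting."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RESULT_COLUMNS)
        for sm in scored:
            writer.writerow(
                [
                    str(sm.motif),
                    len(sm.motif),
                    sm.counts.k_pos,
                    sm.counts.q_neg,
                    sm.counts.m_bak,
                    _fmt(sm.log10_p_neg),
                    _fmt(sm.log10_p_bak),
                    _fmt(sm.z_neg),
                    _fmt(sm.z_bak),
                    _fmt(sm.z),
                ]
            )


def read_results(path) -> list:
    """Read a results TSV back into row dicts (round-trip of write_results)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = tuple(next(reader))
        if header != RESULT_COLUMNS:
            raise SequenceIOError(f"unexpected results header {header!r}")
        for row in reader:
            d = dict(zip(RESULT_COLUMNS, row))
            d["length"] = int(d["length"])
            for key in ("k_pos", "q_neg", "m_bak"):
                d[key] = int(d[key])
            for key in ("log10_pNEG", "log10_pBAK", "zNEG", "zBAK", "z"):
                d[key] = None if d[key] == "NA" else float(d[key])
            rows.append(d)
    return rows
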