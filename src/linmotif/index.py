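"""Window enumeration and per-mask presence counting.

The exhaustive search enumerates every length-l window of the positive set,
passes it through each wildcard mask, and counts for every resulting motif
the number of *distinct proteins* containing it (presence, not occurrences)
in the positives, negatives and background.  Memory stays linear in l
because masks are processed one at a time and each per-mask structure is
released before the next is built.

The per-mask counting structure is a flat encoding of the masked-window
trie: each window's residues at the mask's defined columns are packed into a
single base-21 integer key, and presence counts are obtained from one
vectorized unique pass over (key, protein) pairs.  ``node_count`` reports
the trie-equivalent size bound (entries x (l+1) plus a root) for the memory
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motif import AMINO_ACIDS, Mask, Motif, SENTINEL, WILDCARD, encode_residues


class IndexError_(ValueError):
    pass


def enumerate_windows(record, l: int) -> list:
    """All contiguous (offset, l-mer) windows of a sequence.

    Windows containing sentinel residues are emitted too; they are rejected
    downstream (a sentinel matches no motif position, wildcards included).
    """
    if l < 2:
        raise IndexError_(f"window length must be >= 2, got {l}")
    residues = record.residues if hasattr(record, "residues") else str(record)
    return [(i, residues[i : i + l]) for i in range(len(residues) - l + 1)]


def generate_masks(l: int, mode: str = "canonical") -> list:
    """All wildcard masks of length l, in binary-counting order.

    ``strict`` emits all 2^l boolean vectors.  ``canonical`` pins both ends
    to defined positions (2^(l-2) masks): a terminal wildcard makes a motif
    count-equivalent to a shorter one, so canonical-mode enumeration sweeps
    lengths instead of duplicating statistics.
    """
    if l < 2:
        raise IndexError_(f"mask length must be >= 2, got {l}")
    if mode == "strict":
        free = list(range(l))
    elif mode == "canonical":
        free = list(range(1, l - 1))
    else:
        raise IndexError_(f"unknown mask mode {mode!r}")
    masks = []
    for bits in range(1 << len(free)):
        pattern = [False] * l
        for j, pos in enumerate(free):
            if bits >> j & 1:
                pattern[pos] = True
        masks.append(Mask(tuple(pattern)))
    return masks


@dataclass
class PresenceCount:
    """Distinct-protein counts of one motif in the three partition sets."""

    k_pos: int
    q_neg: int = 0
    m_bak: int = 0

    def __post_init__(self):
        if min(self.k_pos, self.q_neg, self.m_bak) < 0:
            raise IndexError_("negative presence count")


class WindowMatrix:
    """Encoded sliding windows of one length over a set of sequences.

    Sequences are concatenated with sentinel spacers so that windows
    crossing record boundaries (and windows containing genuine sentinel
    residues) are dropped in one filtering pass.
    """

    def __init__(self, records, l: int):
        if l < 2:
            raise IndexError_(f"window length must be >= 2, got {l}")
        self.l = l
        self.n_records = len(records)
        codes_parts, pid_parts, off_parts = [], [], []
        spacer = np.full(l - 1, SENTINEL, dtype=np.uint8)
        spacer_meta = np.full(l - 1, -1, dtype=np.int64)
        for i, rec in enumerate(records):
            c = encode_residues(rec.residues)
            codes_parts.append(c)
            pid_parts.append(np.full(len(c), i, dtype=np.int64))
            off_parts.append(np.arange(len(c), dtype=np.int64))
            if i < len(records) - 1:
                codes_parts.append(spacer)
                pid_parts.append(spacer_meta)
                off_parts.append(spacer_meta)
        if not codes_parts:
            self.windows = np.zeros((0, l), dtype=np.int64)
            self.pid = np.zeros(0, dtype=np.int64)
            self.offset = np.zeros(0, dtype=np.int64)
            return
        codes = np.concatenate(codes_parts)
        pids = np.concatenate(pid_parts)
        offs = np.concatenate(off_parts)
        if len(codes) < l:
            win = np.zeros((0, l), dtype=np.uint8)
            keep = np.zeros(0, dtype=bool)
        else:
            win = np.lib.stride_tricks.sliding_window_view(codes, l)
            keep = ~(win == SENTINEL).any(axis=1)
        self.windows = win[keep].astype(np.int64)
        self.pid = pids[: len(keep)][keep]
        self.offset = offs[: len(keep)][keep]

    def __len__(self) -> int:
        return self.windows.shape[0]

    def keys(self, mask: Mask) -> np.ndarray:
        """Base-21 key of each window's residues at the mask's defined columns.

        Keys fit int64 for up to 13 defined columns; denser masks go through
        the dict-based fallback in :func:`mask_presence`.
        """
        cols = [j for j, b in enumerate(mask) if not b]
        if not cols:
            return np.zeros(len(self), dtype=np.int64)
        if len(cols) > 13:
            raise IndexError_("integer keys support at most 13 defined columns")
        weights = (21 ** np.arange(len(cols), dtype=np.int64))
        return self.windows[:, cols] @ weights


def decode_key(key, mask: Mask) -> Motif:
    """Recover the canonical motif from its per-mask key (int or bytes)."""
    positions = []
    if isinstance(key, (bytes, np.bytes_)):
        it = iter(bytes(key))
        for b in mask:
            positions.append(WILDCARD if b else AMINO_ACIDS[next(it)])
        return Motif(tuple(positions))
    k = int(key)
    for b in mask:
        if b:
            positions.append(WILDCARD)
        else:
            positions.append(AMINO_ACIDS[k % 21])
            k //= 21
    return Motif(tuple(positions))


_EMPTY = np.zeros(0, dtype=np.int64)


def _presence_per_key(keys: np.ndarray, pids: np.ndarray, n_records: int):
    """Distinct-protein count per key via one sort over (key, protein) pairs."""
    if len(keys) == 0:
        return _EMPTY, _EMPTY
    nr = np.int64(n_records)
    combined = np.sort(keys * nr + pids)
    first = np.empty(len(combined), dtype=bool)
    first[0] = True
    np.not_equal(combined[1:], combined[:-1], out=first[1:])
    dedup = combined[first]
    k = dedup // nr
    first = np.empty(len(k), dtype=bool)
    first[0] = True
    np.not_equal(k[1:], k[:-1], out=first[1:])
    starts = np.flatnonzero(first)
    counts = np.empty(len(starts), dtype=np.int64)
    counts[:-1] = starts[1:] - starts[:-1]
    counts[-1] = len(k) - starts[-1]
    return k[starts], counts


def presence_from_keys(
    keys_pos: np.ndarray,
    pid_pos: np.ndarray,
    n_pos: int,
    min_occurrence: int,
    scan_sets=(),
):
    """Prune-then-scan counting given precomputed per-window keys.

    ``scan_sets`` is a sequence of (keys, pids, n_records) triples (e.g.
    negatives then background).  Returns (keys, k_pos, per-scan-set counts,
    n_entries_prepruning); keys sorted ascending.
    """
    ukeys, kpos = _presence_per_key(keys_pos, pid_pos, max(n_pos, 1))
    n_pre = len(ukeys)
    survive = kpos >= min_occurrence
    ukeys, kpos = ukeys[survive], kpos[survive]
    scans = []
    for keys, pids, nrec in scan_sets:
        out = np.zeros(len(ukeys), dtype=np.int64)
        if len(keys) and len(ukeys):
            # match scan windows against the surviving keys first; only the
            # (typically few) hits need the distinct-protein dedup sort
            idx = np.searchsorted(ukeys, keys)
            np.minimum(idx, len(ukeys) - 1, out=idx)
            hit = ukeys[idx] == keys
            ei, ec = _presence_per_key(idx[hit], pids[hit], max(nrec, 1))
            out[ei] = ec
        scans.append(out)
    return ukeys, kpos, scans, n_pre


def _dense_mask_presence(wm_pos, mask, min_occurrence, wm_neg, wm_bak):
    """Dict-based fallback for masks with >13 defined columns (rare: near-
    fully-defined motifs of length 14-15).  Same contract as mask_presence,
    with motif byte strings standing in for integer keys."""
    cols = [j for j, b in enumerate(mask) if not b]

    def tally(wm):
        seen: dict = {}
        if wm is not None and len(wm):
            for row, pid in zip(wm.windows[:, cols].astype(np.uint8), wm.pid):
                seen.setdefault(row.tobytes(), set()).add(int(pid))
        return seen

    pos = tally(wm_pos)
    n_pre = len(pos)
    entries = {k: v for k, v in pos.items() if len(v) >= min_occurrence}
    ukeys = np.array(sorted(entries), dtype=object)
    kpos = np.array([len(entries[k]) for k in ukeys], dtype=np.int64)

    def scan(wm):
        seen = tally(wm)
        return np.array(
            [len(seen.get(k, ())) for k in ukeys], dtype=np.int64
        ) if len(ukeys) else np.zeros(0, dtype=np.int64)

    return ukeys, kpos, scan(wm_neg), scan(wm_bak), n_pre


def mask_presence(
    wm_pos: WindowMatrix,
    mask: Mask,
    min_occurrence: int,
    wm_neg: WindowMatrix | None = None,
    wm_bak: WindowMatrix | None = None,
):
    """One mask pass: build counts over positives, prune, scan other sets.

    Returns (keys, k_pos, q_neg, m_bak, n_entries_prepruning) as parallel
    arrays; ``keys`` is sorted ascending (int64 keys, or motif byte strings
    for masks too dense for integer keys).
    """
    if sum(1 for b in mask if not b) > 13:
        return _dense_mask_presence(wm_pos, mask, min_occurrence, wm_neg, wm_bak)
    ukeys, kpos, scans, n_pre = presence_from_keys(
        wm_pos.keys(mask),
        wm_pos.pid,
        wm_pos.n_records,
        min_occurrence,
        [
            (wm.keys(mask) if wm is not None else _EMPTY,
             wm.pid if wm is not None else _EMPTY,
             wm.n_records if wm is not None else 0)
            for wm in (wm_neg, wm_bak)
        ],
    )
    return ukeys, kpos, scans[0], scans[1], n_pre


@dataclass
class MaskedIndex:
    """Pruned per-mask motif table with presence counts (Fig-style contract)."""

    mask: Mask
    l: int
    entries: dict = field(default_factory=dict)
    node_count: int = 0
    _keys: np.ndarray = None
    _wm_cache: tuple = None

    def complete(self) -> bool:
        return self._wm_cache is None


def build_index(positives, mask: Mask, min_occurrence: int = 3) -> MaskedIndex:
    """Build the pruned counting index over the positives for one mask.

    Entries map canonical motif strings to PresenceCounts with k_pos filled;
    motifs present in fewer than ``min_occurrence`` distinct positive
    proteins are removed before any negative/background scan.
    """
    if not positives:
        raise IndexError_("empty positives set")
    if min_occurrence < 1:
        raise IndexError_("min_occurrence must be >= 1")
    l = len(mask)
    wm = WindowMatrix(positives, l)
    ukeys, kpos, _, _, n_pre = mask_presence(wm, mask, min_occurrence)
    entries = {
        str(decode_key(k, mask)): PresenceCount(k_pos=int(c))
        for k, c in zip(ukeys, kpos)
    }
    return MaskedIndex(
        mask=mask,
        l=l,
        entries=entries,
        node_count=n_pre * (l + 1) + 1,
        _keys=ukeys,
        _wm_cache=None,
    )


def scan_counts(index: MaskedIndex, negatives, background) -> MaskedIndex:
    """Fill q_neg and m_bak by streaming each set's windows through the index."""
    mask, l = index.mask, index.l
    ukeys = index._keys
    dense = ukeys.dtype == object
    cols = [j for j, b in enumerate(mask) if not b]
    for records, attr in ((negatives, "q_neg"), (background, "m_bak")):
        if not records or len(ukeys) == 0:
            continue
        wm = WindowMatrix(records, l)
        if dense:
            seen: dict = {}
            for row, pid in zip(wm.windows[:, cols].astype(np.uint8), wm.pid):
                seen.setdefault(row.tobytes(), set()).add(int(pid))
            counts = np.array([len(seen.get(k, ())) for k in ukeys], dtype=np.int64)
        else:
            sk, sc = _presence_per_key(wm.keys(mask), wm.pid, max(wm.n_records, 1))
            idx = np.searchsorted(ukeys, sk)
            ok = (idx < len(ukeys)) & (ukeys[np.minimum(idx, len(ukeys) - 1)] == sk)
            counts = np.zeros(len(ukeys), dtype=np.int64)
            counts[idx[ok]] = sc[ok]
        for key, c in zip(ukeys, counts):
            if c:
                setattr(index.entries[str(decode_key(key, mask))], attr, int(c))
    return index
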