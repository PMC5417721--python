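"""End-to-end discovery: enumerate -> count -> score -> degenerate -> rank.

For every length in [lmin, lmax] and every wildcard mask of that length,
presence counts are accumulated over the partition, pruned at the minimum
positive occurrence, and scored with the hypergeometric tails.  z-scores
are standardized over the pooled population of all surviving motifs across
masks and lengths, the ranking takes the weaker of the two z-scores, and
the top-ranked seeds containing wildcards are then degenerated into bracket
variants, which are re-standardized against the full population and merged
into the final ranking.

The hot path stays in numpy arrays: masks of one length are visited in
Gray-code order so each mask's window keys follow from the previous mask's
by a single vector add/subtract, and motif strings are only materialized
for the top of the ranking (the part any downstream selection or
evaluation consumes).  Masks are processed one at a time and per-mask
structures are released before the next mask, keeping peak memory linear
in motif length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .degeneration import DegenerationConfig, PartitionMatcher, degenerate
from .index import (
    Mask,
    PresenceCount,
    WindowMatrix,
    decode_key,
    generate_masks,
    mask_presence,
    presence_from_keys,
)
from .motif import AMINO_ACIDS, Motif, WILDCARD, Wildcard
from .scoring import ScoredMotif, ScoringError, log10_hypergeom_tail, score_motif

_CLIP = -320.0  # log10 floor before standardization (keeps z finite)


@dataclass
class RunConfig:
    """Tunable parameters of a discovery run."""

    lmin: int = 3
    lmax: int = 8
    min_occurrence: int = 3
    mask_mode: str = "canonical"          # or "strict" (all 2^l masks)
    background_mode: str = "proteome"     # or "background_only"
    degenerate: bool = True
    degenerate_top: int = 30              # seeds taken from the top of the ranking
    degenerate_screen: int = 0            # extra seeds from the bracket-potential screen
    extension_rounds: int = 0             # re-pad and re-degenerate the best variants
    extension_seeds: int = 8              # variants carried into each extension round
    variant_lmax: int | None = None       # length cap for padded/degenerated variants
    max_bracket: int = 19
    variant_budget: int = 50_000
    improve_rule: str = "composite"
    improve_margin: float = 0.0
    budget_fraction: float = 0.03
    report_top: int = 300                 # ranked motifs materialized in the result
    seed: int = 0

    def __post_init__(self):
        if not (2 <= self.lmin <= self.lmax <= 15):
            raise ValueError(f"need 2 <= lmin <= lmax <= 15, got {self.lmin}..{self.lmax}")
        if not (0 < self.budget_fraction <= 1):
            raise ValueError("budget_fraction outside (0, 1]")
        if self.variant_lmax is None:
            self.variant_lmax = self.lmax
        if not (self.lmax <= self.variant_lmax <= 15):
            raise ValueError("need lmax <= variant_lmax <= 15")
        if self.mask_mode not in ("canonical", "strict"):
            raise ValueError(f"unknown mask mode {self.mask_mode!r}")


@dataclass
class DiscoveryResult:
    ranked: list                         # top ScoredMotifs, best first
    population_size: int
    n_masks: int
    mask_log: list = field(default_factory=list)
    truncated_seeds: int = 0
    config: RunConfig | None = None

    def top(self, n: int = 10) -> list:
        return self.ranked[:n]


def _decode_positional(key: int, mask: Mask) -> Motif:
    """Motif from a positional (21^column) key."""
    positions = []
    k = int(key)
    for j, b in enumerate(mask):
        if b:
            positions.append(WILDCARD)
        else:
            positions.append(AMINO_ACIDS[(k // 21**j) % 21])
    return Motif(tuple(positions))


def _gray_mask_passes(wms, l, mode, min_occurrence):
    """Yield (mask, keys, k_pos, scans, n_pre) for every mask of length l.

    Keys use positional weights (21^column) and are updated incrementally in
    Gray-code order: flipping one position to wildcard subtracts that
    column's contribution.  Requires l <= 13 (int64 key range).
    """
    wm_pos = wms[0]
    free = list(range(l)) if mode == "strict" else list(range(1, l - 1))
    weights = 21 ** np.arange(l, dtype=np.int64)
    prods = [wm.windows * weights if wm is not None else None for wm in wms]
    keys = [p.sum(axis=1) if p is not None else None for p in prods]
    pattern = [False] * l
    n_free = len(free)
    for i in range(1 << n_free):
        if i:
            b = (i & -i).bit_length() - 1  # Gray code: flip bit index of i's lowest set bit
            col = free[b]
            sign = -1 if not pattern[col] else 1
            pattern[col] = not pattern[col]
            for p, kk in zip(prods, keys):
                if p is not None:
                    kk += sign * p[:, col]
        mask = Mask(tuple(pattern))
        ukeys, kpos, scans, n_pre = presence_from_keys(
            keys[0],
            wm_pos.pid,
            wm_pos.n_records,
            min_occurrence,
            [
                (keys[j] if wms[j] is not None else keys[0][:0],
                 wms[j].pid if wms[j] is not None else wm_pos.pid[:0],
                 wms[j].n_records if wms[j] is not None else 0)
                for j in (1, 2)
            ],
        )
        yield mask, ukeys, kpos, scans, n_pre


def _screen_seeds(per_mask, partition, config):
    """Bracket-potential screen: rank padded degeneration seeds population-wide.

    For every enumerated motif and each end, the 20 single-letter extensions
    are themselves enumerated motifs one length up, so their presence counts
    are already available.  Summing the positive counts of the best letters
    (an upper bound on the union) against the matching reference counts
    bounds the enrichment a bracket grown at that position could reach; the
    strongest candidates, padded with terminal wildcards so the position is
    degenerable, are returned as extra seeds for the bracket search.  This
    recovers motifs whose defined skeleton alone is too common to rank
    highly (e.g. a two-letter core flanked by ambiguous positions).
    """
    by_mask = {(t[0], t[2].pattern): t for t in per_mask if t[7]}
    n = partition.n
    N = partition.total
    cands = []
    for t in per_mask:
        l, mask_idx, mask, keys, k, q, m, positional = t
        # dense masks rank well directly when genuinely enriched; the screen
        # exists for sparse skeletons whose flanks carry the signal
        n_defined = sum(1 for b in mask.pattern if not b)
        if not positional or l + 1 > config.lmax or not len(keys) or n_defined > 4:
            continue
        ref = q + m
        for side in ("L", "R"):
            pat = (False,) + mask.pattern if side == "L" else mask.pattern + (False,)
            child = by_mask.get((l + 1, pat))
            if child is None:
                continue
            ckeys, ck, cref = child[3], child[4], child[5] + child[6]
            K = np.zeros((len(keys), 20), dtype=np.int64)
            R = np.zeros((len(keys), 20), dtype=np.int64)
            for a in range(20):
                probe = 21 * keys + a if side == "L" else keys + a * 21**l
                idx = np.searchsorted(ckeys, probe)
                np.minimum(idx, len(ckeys) - 1, out=idx)
                hit = ckeys[idx] == probe
                K[hit, a] = ck[idx[hit]]
                R[hit, a] = cref[idx[hit]]
            order = np.argsort(-K, axis=1, kind="stable")
            Kc = np.cumsum(np.take_along_axis(K, order, axis=1), axis=1)
            Rc = np.cumsum(np.take_along_axis(R, order, axis=1), axis=1)
            np.minimum(Kc, n, out=Kc)
            # log-likelihood-ratio proxy for the tail p-value of (Kc | Rc)
            with np.errstate(divide="ignore", invalid="ignore"):
                llr = Kc * np.log((Kc / n) * (N / np.maximum(Kc + Rc, 1)))
            llr[Kc < max(2, config.min_occurrence)] = 0.0
            best = llr.max(axis=1)
            rows = np.argsort(-best)[: config.degenerate_screen]
            for i in rows:
                if best[i] > 0:
                    cands.append((float(best[i]), l, mask_idx, int(i), side))
    cands.sort(key=lambda c: (-c[0], c[1], c[2], c[3], c[4]))
    by_key = {(t[0], t[1]): t for t in per_mask}
    seeds, seen = [], set()
    for score, l, mask_idx, i, side in cands:
        if len(seeds) >= config.degenerate_screen:
            break
        t = by_key[(l, mask_idx)]
        core = _decode_positional(t[3][i], t[2])
        pad = min(2, config.variant_lmax - l)
        pads = (WILDCARD,) * pad
        positions = pads + core.positions if side == "L" else core.positions + pads
        motif = Motif(positions)
        name = str(motif)
        if name in seen:
            continue
        seen.add(name)
        seeds.append(ScoredMotif(motif=motif, counts=None, log10_p_neg=None, log10_p_bak=None))
    return seeds


def _pvalue_arrays(k, q, m, partition, background_mode):
    """Vector log10 p-values via the cached scalar tail on deduplicated triples."""
    n, p, b = partition.n, partition.p, partition.b
    combo = (k * np.int64(p + 1) + q) * np.int64(b + 1) + m
    uniq, inverse = np.unique(combo, return_inverse=True)
    pn_u = np.empty(len(uniq))
    pb_u = np.empty(len(uniq))
    for j, c in enumerate(uniq):
        mm = int(c % (b + 1))
        rest = int(c // (b + 1))
        qq = int(rest % (p + 1))
        kk = int(rest // (p + 1))
        pn_u[j] = log10_hypergeom_tail(kk, n + p, kk + qq, n) if p > 0 else np.nan
        if b > 0:
            if background_mode == "proteome":
                pb_u[j] = log10_hypergeom_tail(kk, n + p + b, kk + qq + mm, n)
            else:
                pb_u[j] = log10_hypergeom_tail(kk, n + b, kk + mm, n)
        else:
            pb_u[j] = np.nan
    return pn_u[inverse], pb_u[inverse]


def discover(partition, config: RunConfig | None = None) -> DiscoveryResult:
    """Run the full exhaustive search on one proteome partition."""
    config = config or RunConfig()
    if partition.p == 0 and partition.b == 0:
        raise ScoringError("need a non-empty negatives or background set")

    per_mask = []    # (l, mask_idx, mask, keys, k, q, m, positional)
    mask_log = []
    n_masks = 0
    for l in range(config.lmin, config.lmax + 1):
        wms = (
            WindowMatrix(partition.positives, l),
            WindowMatrix(partition.negatives, l) if partition.p else None,
            WindowMatrix(partition.background, l) if partition.b else None,
        )
        if l <= 13:
            passes = (
                (mask, ukeys, kpos, scans, n_pre, True)
                for mask, ukeys, kpos, scans, n_pre in _gray_mask_passes(
                    wms, l, config.mask_mode, config.min_occurrence
                )
            )
        else:
            passes = (
                (mask, *_unpack(mask_presence(
                    wms[0], mask, config.min_occurrence, wms[1], wms[2]
                )), False)
                for mask in generate_masks(l, config.mask_mode)
            )
        for mask_idx, (mask, ukeys, kpos, scans, n_pre, positional) in enumerate(passes):
            n_masks += 1
            mask_log.append(
                {
                    "l": l,
                    "mask": str(mask),
                    "entries_prepruning": int(n_pre),
                    "entries": int(len(ukeys)),
                    "node_count": int(n_pre * (l + 1) + 1),
                }
            )
            if len(ukeys):
                per_mask.append(
                    (l, mask_idx, mask, ukeys, kpos, scans[0], scans[1], positional)
                )

    if not per_mask:
        return DiscoveryResult(
            ranked=[], population_size=0, n_masks=n_masks, mask_log=mask_log,
            config=config,
        )

    k_all = np.concatenate([t[4] for t in per_mask])
    q_all = np.concatenate([t[5] for t in per_mask])
    m_all = np.concatenate([t[6] for t in per_mask])
    pn_all, pb_all = _pvalue_arrays(k_all, q_all, m_all, partition, config.background_mode)

    have_neg, have_bak = partition.p > 0, partition.b > 0

    class _Axis:
        """Population mean/sd of -log10 p for one reference axis."""

        def __init__(self, pop):
            x = -np.maximum(pop, _CLIP)
            self.mean = float(np.mean(x))
            self.sd = float(np.std(x))

        def z(self, log10_p):
            if self.sd == 0.0:
                return np.zeros_like(np.asarray(log10_p, dtype=float))
            return (-np.maximum(log10_p, _CLIP) - self.mean) / self.sd

    axis_neg = _Axis(pn_all) if have_neg else None
    axis_bak = _Axis(pb_all) if have_bak else None
    if have_neg and have_bak:
        z = np.minimum(axis_neg.z(pn_all), axis_bak.z(pb_all))
    elif have_neg:
        z = axis_neg.z(pn_all)
    else:
        z = axis_bak.z(pb_all)

    # deterministic full ordering: z desc, then stronger p_NEG (or p_BAK),
    # then (l, mask, key) as a reproducible final tie-break
    p_primary = pn_all if have_neg else pb_all
    l_arr = np.concatenate([np.full(len(t[3]), t[0], dtype=np.int64) for t in per_mask])
    mask_arr = np.concatenate([np.full(len(t[3]), t[1], dtype=np.int64) for t in per_mask])
    key_arr = np.concatenate(
        [t[3] if t[3].dtype != object else np.arange(len(t[3])) for t in per_mask]
    )
    order = np.lexsort((key_arr, mask_arr, l_arr, np.maximum(p_primary, _CLIP), -z))

    # materialize the top of the ranking
    bounds = np.cumsum([0] + [len(t[3]) for t in per_mask])
    n_top = min(len(order), max(config.report_top, config.degenerate_top * 4))
    top = []
    for idx in order[:n_top]:
        block = int(np.searchsorted(bounds, idx, side="right")) - 1
        t = per_mask[block]
        key = t[3][idx - bounds[block]]
        motif = (
            _decode_positional(key, t[2]) if t[7] else decode_key(key, t[2])
        )
        top.append(
            ScoredMotif(
                motif=motif,
                counts=PresenceCount(
                    k_pos=int(k_all[idx]), q_neg=int(q_all[idx]), m_bak=int(m_all[idx])
                ),
                log10_p_neg=float(pn_all[idx]) if have_neg else None,
                log10_p_bak=float(pb_all[idx]) if have_bak else None,
            )
        )

    # degeneration of the top wildcard-bearing seeds
    truncated = 0
    variants = {}
    if config.degenerate:
        deg_cfg = DegenerationConfig(
            max_bracket=config.max_bracket,
            variant_budget=config.variant_budget,
            improve_rule=config.improve_rule,
            improve_margin=config.improve_margin,
            background_mode=config.background_mode,
        )
        seen = {str(sm.motif) for sm in top}
        seeds = [sm for sm in top if sm.motif.n_wildcards() > 0][: config.degenerate_top]
        if config.degenerate_screen > 0:
            have = {str(sm.motif) for sm in seeds}
            for sm in _screen_seeds(per_mask, partition, config):
                if str(sm.motif) not in have:
                    seeds.append(sm)

        matcher = PartitionMatcher(partition)

        def strip_pads(var):
            # terminal wildcards were scaffolding for the bracket search; the
            # trimmed core is count-equivalent (modulo sequence-edge margins)
            # and covers exactly the constrained columns, so report that
            pos = list(var.motif.positions)
            while pos and isinstance(pos[0], Wildcard):
                pos.pop(0)
            while pos and isinstance(pos[-1], Wildcard):
                pos.pop()
            if len(pos) < 2 or len(pos) == len(var.motif):
                return var
            motif = Motif(tuple(pos))
            sets = matcher.match_rows(motif, [])
            counts = PresenceCount(
                *(int(np.unique(pids).size) for pids, _ in sets)
            )
            pn, pb = score_motif(counts, partition, config.background_mode)
            return ScoredMotif(motif=motif, counts=counts, log10_p_neg=pn,
                               log10_p_bak=pb, family=var.family)

        def run_seeds(seed_list):
            nonlocal truncated
            new = []
            for seed in seed_list:
                res = degenerate(seed, partition, deg_cfg, matcher=matcher)
                truncated += int(res.truncated)
                family = seed.family or str(seed.motif)
                for var in res.variants:
                    var.family = family
                    var = strip_pads(var)
                    name = str(var.motif)
                    if name not in seen and name not in variants:
                        variants[name] = var
                        new.append(var)
            return new

        fresh = run_seeds(seeds)

        # extension rounds: pad the strongest improved variants with fresh
        # terminal wildcards and search again, so bracket chains can grow
        # beyond the seed's own span (flanking positions of long motifs)
        def worse_p(sm):
            ps = [p for p in (sm.log10_p_neg, sm.log10_p_bak) if p is not None]
            return max(ps)

        padded_seen = set()
        for _ in range(config.extension_rounds):
            # one representative per seed family, best families first, so a
            # single strong family cannot monopolize the extension budget
            by_family = {}
            for sm in sorted(fresh, key=worse_p):
                by_family.setdefault(sm.family, []).append(sm)
            ordered = sorted(by_family.values(), key=lambda g: worse_p(g[0]))
            best = []
            depth = 0
            while len(best) < config.extension_seeds:
                added = False
                for group in ordered:
                    if depth < len(group) and len(best) < config.extension_seeds:
                        best.append(group[depth])
                        added = True
                if not added:
                    break
                depth += 1
            ext_seeds = []
            for sm in best:
                l = len(sm.motif)
                room = config.variant_lmax - l
                pad_shapes = ((2, 0), (0, 2)) if room >= 2 else (
                    ((1, 0), (0, 1)) if room == 1 else ()
                )
                for a, b in pad_shapes:
                    motif = Motif(
                        (WILDCARD,) * a + sm.motif.positions + (WILDCARD,) * b
                    )
                    name = str(motif)
                    if name in padded_seen or name in variants or name in seen:
                        continue
                    padded_seen.add(name)
                    ext_seeds.append(
                        ScoredMotif(motif=motif, counts=None, log10_p_neg=None,
                                    log10_p_bak=None, family=sm.family)
                    )
            if not ext_seeds:
                break
            fresh = run_seeds(ext_seeds)

    # re-standardize everything over the pooled population (enumerated + variants)
    var_list = list(variants.values())
    if var_list:
        if have_neg:
            axis_neg = _Axis(
                np.concatenate([pn_all, [v.log10_p_neg for v in var_list]])
            )
        if have_bak:
            axis_bak = _Axis(
                np.concatenate([pb_all, [v.log10_p_bak for v in var_list]])
            )
    merged = top + var_list
    for sm in merged:
        zs = []
        if have_neg:
            sm.z_neg = float(axis_neg.z(np.array([sm.log10_p_neg]))[0])
            zs.append(sm.z_neg)
        if have_bak:
            sm.z_bak = float(axis_bak.z(np.array([sm.log10_p_bak]))[0])
            zs.append(sm.z_bak)
        sm.z = min(zs)
    merged.sort(key=ScoredMotif.sort_key)

    return DiscoveryResult(
        ranked=merged[: config.report_top],
        population_size=len(k_all) + len(var_list),
        n_masks=n_masks,
        mask_log=mask_log,
        truncated_seeds=truncated,
        config=config,
    )


def _unpack(res):
    ukeys, kpos, qneg, mbak, n_pre = res
    return ukeys, kpos, (qneg, mbak), n_pre
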