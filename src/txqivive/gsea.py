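"""Pre-ranked gene-set enrichment on the BMDL-ordered gene list.

The ranked list places the most sensitive genes (lowest BMDL) first, with
ranking score s_g = -log10(BMDL_g). Enrichment uses the weighted
Kolmogorov-Smirnov running statistic: walking down the list, set members
("hits") add |s_g|^p normalized over the set, non-members subtract
1/(N - N_set); the enrichment score (ES) is the maximum signed deviation.
Significance comes from a gene-label permutation null preserving set sizes,
normalized scores (NES) and FDR q-values follow the standard two-tailed
procedure computed separately for positive- and negative-ES sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bmc import GeneBMDRecord

__all__ = [
    "RankedGeneList",
    "EnrichmentResult",
    "collapse_probes",
    "ranking_score",
    "build_ranked_list",
    "enrichment_score",
    "significance",
    "leading_edge",
    "most_sensitive_gene",
]


@dataclass
class RankedGeneList:
    """Gene symbols ordered most-sensitive first with ranking scores."""

    genes: list[str]
    scores: np.ndarray          # non-increasing down the list
    bmdl: dict[str, float] = field(default_factory=dict)
    responsive: set | None = None   # symbols passing the BMC filters
                                    # (None = eligibility not tracked)

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list contains duplicate symbols")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing down the list")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    q: float
    size: int
    leading_edge: list[str]


def collapse_probes(
    bmdl_by_probe: Mapping[str, float],
    symbol_map: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Collapse duplicated probes to unique symbols, averaging their BMDLs.

    Probes missing from ``symbol_map`` are dropped (the count is implicit in
    the output size). Infinite sentinels propagate: a symbol whose probes
    are all undefined stays undefined; finite probes dominate the mean of a
    mixed group (arithmetic mean over finite values).
    """
    if not bmdl_by_probe:
        raise ValueError("empty probe table")
    groups: dict[str, list[float]] = {}
    for probe, bmdl in bmdl_by_probe.items():
        symbol = symbol_map.get(probe) if symbol_map is not None else probe
        if symbol is None:
            continue
        groups.setdefault(symbol, []).append(float(bmdl))
    out = {}
    for symbol, vals in groups.items():
        finite = [v for v in vals if np.isfinite(v)]
        out[symbol] = float(np.mean(finite)) if finite else np.inf
    return out


def ranking_score(bmdl: np.ndarray, eps: float = 0.05) -> np.ndarray:
    """s = -log10(BMDL); undefined (infinite) BMDLs map just below the
    smallest finite score so they sit at the bottom of the list."""
    bmdl = np.asarray(bmdl, dtype=float)
    if np.any(bmdl[np.isfinite(bmdl)] <= 0):
        raise ValueError("finite BMDL values must be positive")
    s = np.full(len(bmdl), np.nan)
    finite = np.isfinite(bmdl)
    s[finite] = -np.log10(bmdl[finite])
    if (~finite).any():
        floor = (s[finite].min() if finite.any() else 0.0) - eps
        s[~finite] = floor
    return s


def build_ranked_list(
    records: Sequence[GeneBMDRecord],
    symbol_map: Mapping[str, str] | None = None,
) -> RankedGeneList:
    """Collapse probe-level BMC records to a symbol-level ranked list."""
    collapsed = collapse_probes(
        {r.gene_id: r.bmdl_for_ranking for r in records}, symbol_map
    )
    responsive = set()
    for r in records:
        if getattr(r, "responsive", False):
            symbol = symbol_map.get(r.gene_id) if symbol_map else r.gene_id
            if symbol is not None:
                responsive.add(symbol)
    symbols = sorted(collapsed)          # lexicographic tie-break
    bmdl = np.array([collapsed[s] for s in symbols])
    scores = ranking_score(bmdl)
    order = np.lexsort((symbols, -scores))
    genes = [symbols[i] for i in order]
    return RankedGeneList(genes, scores[order],
                          dict(zip(genes, bmdl[order])), responsive)


# --------------------------------------------------------------------------
# weighted KS statistic
# --------------------------------------------------------------------------


def _running_sum(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> np.ndarray:
    """Running hit-minus-miss profile; sums to 0 over the full list."""
    n = len(scores)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("set must intersect, not cover, the universe")
    w = np.abs(scores) ** weight
    hit_inc = np.where(hit_mask, w, 0.0)
    denom = hit_inc.sum()
    if denom <= 0:
        # all-zero weights (only possible with weight>0 and zero scores):
        # fall back to the unweighted statistic
        hit_inc = hit_mask.astype(float)
        denom = hit_inc.sum()
    miss_inc = np.where(hit_mask, 0.0, 1.0 / (n - n_hit))
    return np.cumsum(hit_inc / denom - miss_inc)


def enrichment_score(
    ranked: RankedGeneList | None,
    gene_set: Sequence[str],
    weight: float = 1.0,
    scores: np.ndarray | None = None,
    hit_mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray, int]:
    """Weighted-KS enrichment score.

    Returns ``(ES, running profile, peak index)``; ES is the profile value
    of largest magnitude (signed). With weight p=0 this is the classic KS
    statistic. Callers may pass precomputed ``scores``/``hit_mask`` arrays
    (the permutation loop does) instead of a ranked list + set.
    """
    if hit_mask is None:
        assert ranked is not None
        scores = ranked.scores
        members = set(gene_set)
        hit_mask = np.fromiter(
            (g in members for g in ranked.genes), dtype=bool, count=len(ranked)
        )
        if not hit_mask.any():
            raise ValueError("gene set does not intersect the universe")
    assert scores is not None
    profile = _running_sum(scores, hit_mask, weight)
    peak = int(np.argmax(np.abs(profile)))
    return float(profile[peak]), profile, peak


def leading_edge(
    ranked: RankedGeneList,
    gene_set: Sequence[str],
    profile: np.ndarray,
    peak: int,
) -> list[str]:
    """Set members contributing to the ES peak: at/before the peak for a
    positive ES, at/after the trough for a negative ES."""
    members = set(gene_set)
    es = profile[peak]
    if es >= 0:
        idx = range(0, peak + 1)
    else:
        idx = range(peak, len(ranked))
    return [ranked.genes[i] for i in idx if ranked.genes[i] in members]


# --------------------------------------------------------------------------
# permutation significance
# --------------------------------------------------------------------------


def significance(
    ranked: RankedGeneList,
    sets: Mapping[str, Sequence[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 149,
    min_size: int = 15,
    max_size: int = 500,
) -> list[EnrichmentResult]:
    """Permutation p, NES and FDR q for every admissible gene set.

    The null randomizes set membership over the ranked universe preserving
    set sizes (gene-label permutation). NES = ES / mean(|null ES| of the
    same sign); nominal p is the same-sign null tail; q follows the
    normalized tail-area FDR of the standard procedure, per sign class,
    with monotone enforcement. Results are ordered by q then |NES|.
    """
    rng = np.random.default_rng(seed)
    n = len(ranked)
    universe = set(ranked.genes)
    gene_index = {g: i for i, g in enumerate(ranked.genes)}
    scores = ranked.scores

    admissible: list[tuple[str, np.ndarray, int]] = []
    for name, members in sets.items():
        present = sorted(universe.intersection(members))
        if not (min_size <= len(present) <= max_size):
            continue
        if len(present) >= n:
            raise ValueError(f"set {name!r} covers the whole universe")
        mask = np.zeros(n, dtype=bool)
        mask[[gene_index[g] for g in present]] = True
        admissible.append((name, mask, len(present)))
    if not admissible:
        return []

    # observed statistics
    observed = []
    for name, mask, size in admissible:
        es, profile, peak = enrichment_score(
            None, (), weight, scores=scores, hit_mask=mask
        )
        observed.append((name, es, profile, peak, size))

    # permutation null, one batch of random membership masks per set size
    sizes = sorted({size for _, _, size in admissible})
    null_by_size: dict[int, np.ndarray] = {}
    w_all = np.abs(scores) ** weight
    for size in sizes:
        null = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(n, size=size, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            hit_inc = w_all * mask
            denom = hit_inc.sum()
            if denom <= 0:
                hit_inc = mask.astype(float)
                denom = hit_inc.sum()
            miss_inc = (~mask).astype(float) / (n - size)
            prof = np.cumsum(hit_inc / denom - miss_inc)
            null[b] = prof[np.argmax(np.abs(prof))]
        null_by_size[size] = null

    # NES for observed and null
    results = []
    null_nes_all = []
    for name, es, profile, peak, size in observed:
        null = null_by_size[size]
        same_sign = null[null * np.sign(es) > 0] if es != 0 else null
        if len(same_sign) == 0:
            nes = 0.0
            p = 1.0 / (n_perm + 1)
        else:
            denom = np.abs(same_sign).mean()
            nes = es / denom if denom > 0 else 0.0
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + len(same_sign))
        results.append([name, es, nes, float(p), size, profile, peak])
        pos = null[null > 0]
        neg = null[null < 0]
        nes_null = np.concatenate(
            [
                pos / pos.mean() if len(pos) else np.empty(0),
                neg / np.abs(neg).mean() if len(neg) else np.empty(0),
            ]
        )
        null_nes_all.append(nes_null)
    null_nes = np.concatenate(null_nes_all)
    obs_nes = np.array([r[2] for r in results])

    # normalized tail-area FDR per sign class
    qs = np.ones(len(results))
    for sign in (1, -1):
        idx = [i for i, v in enumerate(obs_nes) if np.sign(v) == sign]
        if not idx:
            continue
        null_side = null_nes[np.sign(null_nes) == sign]
        obs_side = obs_nes[np.sign(obs_nes) == sign]
        for i in idx:
            thr = abs(obs_nes[i])
            if len(null_side):
                num = np.mean(np.abs(null_side) >= thr)
            else:
                num = 0.0
            den = np.mean(np.abs(obs_side) >= thr)
            qs[i] = min(1.0, num / den) if den > 0 else 1.0
        # monotone in |NES| within the sign class
        order = np.argsort([-abs(obs_nes[i]) for i in idx])
        running = 0.0
        for j in order:
            running = max(running, qs[idx[j]])
            qs[idx[j]] = running

    out = []
    for (name, es, nes, p, size, profile, peak), q in zip(results, qs):
        le = leading_edge(ranked, _set_members(sets[name]), profile, peak)
        out.append(EnrichmentResult(name, es, nes, p, float(q), size, le))
    out.sort(key=lambda r: (r.q, -abs(r.nes), r.name))
    return out


def _set_members(members: Sequence[str]) -> list[str]:
    return list(members)


def most_sensitive_gene(
    results: Sequence[EnrichmentResult],
    ranked: RankedGeneList,
    sets: Mapping[str, Sequence[str]],
    q_threshold: float = 0.1,
) -> tuple[dict[str, tuple[str, float]], tuple[str, str, float] | None]:
    """Most sensitive (lowest collapsed BMDL) member gene of each
    significant pathway, and the global point-of-departure gene.

    Candidate genes are restricted to those flagged responsive by the BMC
    filters (when tracked): a BMDL the workflow's own filters rejected is
    not a defensible point of departure. A pathway with no responsive
    member falls back to all present members.

    Returns ``(per_pathway, pod)`` where ``per_pathway`` maps pathway name
    to ``(gene, BMDL)`` and ``pod`` is ``(pathway, gene, BMDL)`` for the
    lowest member BMDL among significant pathways, or None when nothing is
    significant.
    """
    per_pathway: dict[str, tuple[str, float]] = {}
    universe = set(ranked.genes)
    for r in results:
        if r.q >= q_threshold:
            continue
        present = sorted(universe.intersection(sets[r.name]))
        if not present:
            continue
        if ranked.responsive is not None:
            eligible = sorted(ranked.responsive.intersection(present))
            present = eligible or present
        gene = min(present, key=lambda g: (ranked.bmdl.get(g, np.inf), g))
        per_pathway[r.name] = (gene, float(ranked.bmdl.get(gene, np.inf)))
    if not per_pathway:
        return {}, None
    pod_pathway = min(
        per_pathway, key=lambda k: (per_pathway[k][1], per_pathway[k][0], k)
    )
    gene, bmdl = per_pathway[pod_pathway]
    return per_pathway, (pod_pathway, gene, bmdl)
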