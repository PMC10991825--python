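"""Synthetic concentration-response data with known ground truth.

Generates the three inputs every downstream stage needs, without any
external download: (i) gene x (concentration, replicate) expression
matrices in which a minority of genes follow monotone sigmoidal
concentration-response curves at known benchmark concentrations and the
rest are flat; (ii) GMT gene-set collections that are enriched (or not)
in the sensitive genes; (iii) virtual-population parameter tables with a
known external dose whose steady-state concentrations become
reverse-dosimetry targets.

Defaults mirror the study conditions: the 8-concentration design
0.02-50 µM plus vehicle control, 3 replicates, a 14% responsive-gene
fraction, and Gaussian log2-scale noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ConcentrationResponseDataset
from .pbk import (
    PopulationPriors,
    VirtualPopulation,
    sample_population,
    steady_state,
)

__all__ = [
    "SyntheticTruth",
    "generate_expression_matrix",
    "generate_count_matrix",
    "generate_gene_sets",
    "generate_population_truth",
    "true_bmc_hill",
]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated expression matrix."""

    genes: pd.DataFrame      # gene_id, responsive, baseline, effect,
                             # direction, hill_k, hill_n, true_bmc
    noise_sd: float
    seed: int
    family: str = "hill"
    enriched_sets: list = None  # filled by generate_gene_sets

    @property
    def responsive_ids(self) -> list[str]:
        g = self.genes
        return list(g.loc[g["responsive"], "gene_id"])

    @property
    def responsive_fraction(self) -> float:
        return float(self.genes["responsive"].mean())


def true_bmc_hill(k: float, n: float, effect: float, bmr: float) -> float:
    """Concentration where a Hill curve |b|*x^n/(k^n+x^n) departs from
    baseline by ``bmr`` (NaN when the effect never reaches it)."""
    if abs(effect) <= bmr:
        return np.nan
    u = bmr / abs(effect)
    return k * (u / (1.0 - u)) ** (1.0 / n)


def _hill_k_for_bmc(bmc: float, n: float, effect: float, bmr: float) -> float:
    """Invert :func:`true_bmc_hill`: half-max k putting the true BMC at the
    requested concentration."""
    u = bmr / abs(effect)
    return bmc * ((1.0 - u) / u) ** (1.0 / n)


def generate_expression_matrix(
    n_genes: int = 300,
    concentrations: np.ndarray | list = (
        0.0, 0.02, 0.1, 0.2, 1.0, 2.0, 10.0, 20.0, 50.0
    ),
    responsive_fraction: float = 0.14,
    noise_sd: float = 0.15,
    n_replicates: int = 3,
    seed: int = 0,
    effect_size: float = 1.0,
    family: str = "hill",
    timepoint: str = "day10",
) -> tuple[ConcentrationResponseDataset, SyntheticTruth]:
    """Simulate a log2-scale expression matrix with known gene truths.

    Responsive genes follow a Hill curve (optionally a 5-parameter
    exponential via ``family="exp5"`` to exercise model competition on
    mis-specified truths); their true BMC (at BMR = ``noise_sd``, i.e.
    1 noise SD) is drawn log-uniformly strictly inside the tested range.
    Null genes are flat. Noise is i.i.d. Gaussian on the log2 scale.
    Deterministic given ``seed``.
    """
    conc = np.asarray(sorted(concentrations), dtype=float)
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    if len(conc[conc > 0]) < 4:
        raise ValueError("need at least 4 non-control concentrations")
    if not 0 < responsive_fraction < 1:
        raise ValueError("responsive_fraction must lie in (0, 1)")
    n_resp = int(round(responsive_fraction * n_genes))
    if n_resp < 1:
        raise ValueError("responsive_fraction * n_genes < 1")
    if family not in ("hill", "exp5"):
        raise ValueError(f"unknown truth family {family!r}")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    responsive = np.zeros(n_genes, dtype=bool)
    responsive[rng.choice(n_genes, size=n_resp, replace=False)] = True

    baseline = rng.uniform(6.0, 10.0, size=n_genes)
    effect = np.where(
        responsive,
        effect_size * rng.uniform(0.75, 1.25, size=n_genes),
        0.0,
    )
    direction = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    direction[~responsive] = 0.0
    hill_n = rng.uniform(1.0, 3.0, size=n_genes)
    pos = conc[conc > 0]
    bmr = noise_sd if noise_sd > 0 else 0.05 * effect_size
    lo, hi = pos.min() * 1.5, pos.max() / 1.5
    true_bmc = np.full(n_genes, np.nan)
    true_bmc[responsive] = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=n_resp)
    )
    hill_k = np.full(n_genes, np.nan)
    for i in np.flatnonzero(responsive):
        hill_k[i] = _hill_k_for_bmc(true_bmc[i], hill_n[i], effect[i], bmr)

    cols = pd.MultiIndex.from_tuples(
        [(c, str(r + 1)) for c in conc for r in range(n_replicates)],
        names=["concentration", "replicate"],
    )
    x = np.array([c for c, _ in cols])
    signal = np.tile(baseline[:, None], (1, len(cols)))
    for i in np.flatnonzero(responsive):
        if family == "hill":
            xn = np.power(x, hill_n[i])
            shape = xn / (hill_k[i] ** hill_n[i] + xn)
        else:
            # exp5-shaped truth 1 - exp(-(x/lam)^h), scale chosen so the
            # recorded true BMC is exact for this family too
            u = bmr / abs(effect[i])
            lam = true_bmc[i] / (-np.log(1.0 - u)) ** (1.0 / hill_n[i])
            shape = 1.0 - np.exp(-np.power(x / lam, hill_n[i]))
        signal[i] += direction[i] * effect[i] * shape
    values = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    df = pd.DataFrame(values, index=gene_ids, columns=cols)
    ds = ConcentrationResponseDataset(df, timepoint=timepoint)
    truth = SyntheticTruth(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "responsive": responsive,
                "baseline": baseline,
                "effect": effect,
                "direction": direction.astype(int),
                "hill_k": hill_k,
                "hill_n": hill_n,
                "true_bmc": true_bmc,
            }
        ),
        noise_sd=noise_sd,
        seed=seed,
        family=family,
    )
    return ds, truth


def generate_count_matrix(
    *args, library_size_cv: float = 0.3, seed: int = 0, **kwargs
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Count-level variant for testing normalization: the log2-scale signal
    is exponentiated to expected counts and scaled by lognormal per-sample
    library-size factors."""
    ds, truth = generate_expression_matrix(*args, seed=seed, **kwargs)
    rng = np.random.default_rng(seed + 1)
    n_samples = ds.values.shape[1]
    sd = np.sqrt(np.log(1.0 + library_size_cv**2))
    size_factors = np.exp(rng.normal(0.0, sd, size=n_samples))
    counts = np.round(np.power(2.0, ds.values.to_numpy()) * size_factors)
    return (
        pd.DataFrame(
            counts, index=ds.values.index, columns=ds.values.columns
        ),
        truth,
    )


def generate_gene_sets(
    truth: SyntheticTruth,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (15, 50),
    enriched_sets: int = 2,
    seed: int = 0,
    enriched_member_fraction: float = 0.8,
) -> dict[str, list[str]]:
    """GMT-style gene-set collection with known enrichment truth.

    Enriched sets draw ``enriched_member_fraction`` (>= 0.7) of their
    members from the low-BMC half of the responsive genes; null sets draw
    uniformly from the whole universe. Set names carry an ``ENR``/``NULL``
    prefix and the truth object records the enriched names.
    """
    if enriched_member_fraction < 0.7:
        raise ValueError("enriched sets must draw >=70% from responsive genes")
    rng = np.random.default_rng(seed)
    g = truth.genes
    universe = list(g["gene_id"])
    resp = g.loc[g["responsive"]].sort_values("true_bmc")
    all_resp = list(resp["gene_id"])
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set sizes exceed the gene universe")
    sets: dict[str, list[str]] = {}
    enriched_names = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < enriched_sets:
            n_from_pool = int(np.ceil(enriched_member_fraction * size))
            if n_from_pool > len(all_resp):
                raise ValueError(
                    "not enough responsive genes to populate enriched sets"
                )
            # draw from the most sensitive (lowest true BMC) responsive
            # genes, with a little slack so enriched sets are not identical
            pool = all_resp[: min(len(all_resp), 2 * n_from_pool)]
            members = list(
                rng.choice(pool, size=n_from_pool, replace=False)
            )
            rest = [u for u in universe if u not in set(members)]
            members += list(
                rng.choice(rest, size=size - n_from_pool, replace=False)
            )
            name = f"ENR_SET_{i:02d}"
            enriched_names.append(name)
        else:
            members = list(rng.choice(universe, size=size, replace=False))
            name = f"NULL_SET_{i:02d}"
        sets[name] = sorted(members)
    truth.enriched_sets = enriched_names
    return sets


def generate_population_truth(
    n: int,
    seed: int = 0,
    true_dose: float = 1.0,
    priors: PopulationPriors | None = None,
    output: str = "liver_efferent_free",
) -> tuple[VirtualPopulation, float, np.ndarray]:
    """Virtual population plus forward-simulated reverse-dosimetry targets.

    Samples ``n`` individuals from the same priors as the QIVIVE stage,
    forward-simulates the chosen true drinking-water dose (µg/L) to each
    individual's steady-state concentration, and returns those
    concentrations as targets whose reverse dosimetry should recover the
    dose.
    """
    pop = sample_population(n, priors=priors, seed=seed)
    targets = np.array(
        [
            steady_state(pop.individual(i), true_dose, output=output)
            for i in range(n)
        ]
    )
    return pop, true_dose, targets
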