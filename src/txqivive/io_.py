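"""Readers/writers, count normalization and exposure-timepoint selection.

Expression matrices are TSV/CSV with genes in rows and one column per
(concentration, replicate) sample, headed ``gene_id, <conc>_<rep>, ...``
(e.g. ``0.02_1``, ``0.02_2``, ``0_1`` for the vehicle control). Gene sets
use the GMT dialect (name, description, members, tab-separated).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ConcentrationResponseDataset

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "median_of_ratios_size_factors",
    "normalize_counts",
    "select_timepoint",
    "read_gmt",
    "write_gmt",
    "write_table",
    "write_run_summary",
    "get_logger",
]

log = logging.getLogger("txqivive.io")

_COLUMN_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*_\s*(\S+)\s*$")


def get_logger(stage: str, level: int = logging.INFO) -> logging.Logger:
    """Timestamped, stage-tagged logger."""
    logger = logging.getLogger(f"txqivive.{stage}")
    if not logging.getLogger("txqivive").handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter(
                "%(asctime)s [%(name)s] %(levelname)s: %(message)s"
            )
        )
        root = logging.getLogger("txqivive")
        root.addHandler(handler)
        root.setLevel(level)
    return logger


def _parse_columns(columns: Iterable[str]) -> pd.MultiIndex:
    pairs = []
    for col in columns:
        m = _COLUMN_RE.match(str(col))
        if m is None:
            raise ValueError(
                f"unparseable sample column {col!r}; expected '<conc>_<rep>'"
            )
        pairs.append((float(m.group(1)), m.group(2)))
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate sample columns after parsing")
    return pd.MultiIndex.from_tuples(pairs, names=["concentration", "replicate"])


def read_expression_matrix(
    path: str | Path,
    timepoint: str = "",
    exclude_cytotoxic: Sequence[float] = (100.0,),
    require_control: bool = True,
) -> ConcentrationResponseDataset:
    """Read a TSV/CSV expression matrix into a dataset.

    Columns listed in ``exclude_cytotoxic`` (nominal µM) are dropped; the
    default removes the 100 µM group excluded for cytotoxicity in the
    source design. Concentrations unordered on disk are sorted ascending.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    df.columns = _parse_columns(df.columns)
    conc = np.asarray(df.columns.get_level_values(0), dtype=float)
    if exclude_cytotoxic:
        excl = np.asarray(list(exclude_cytotoxic), dtype=float)
        keep = ~np.isclose(conc[:, None], excl[None, :]).any(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            log.info(
                "dropping %d columns at excluded concentrations %s",
                dropped,
                sorted(set(conc[~keep])),
            )
        df = df.loc[:, keep]
        conc = conc[keep]
    if require_control and not (conc == 0).any():
        raise ValueError("no vehicle-control (0 µM) columns found")
    ds = ConcentrationResponseDataset(df, timepoint=timepoint)
    return ds


def write_expression_matrix(
    ds: ConcentrationResponseDataset, path: str | Path
) -> None:
    """Write a dataset back to the TSV/CSV dialect ``read_expression_matrix``
    accepts (lossless round trip up to float repr)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    flat = ds.values.copy()
    flat.columns = [
        f"{c:g}_{r}" for c, r in zip(
            flat.columns.get_level_values(0), flat.columns.get_level_values(1)
        )
    ]
    flat.index.name = "gene_id"
    flat.to_csv(path, sep=sep)


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """Per-sample size factors: median across reference genes (all-positive
    counts) of count / geometric-mean-of-gene."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "every gene contains a zero count; no reference genes for "
            "median-of-ratios — supply a pre-normalized matrix instead"
        )
    ref = counts[positive]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    return np.exp(np.median(np.log(ref) - log_geo_mean, axis=0))


def normalize_counts(
    raw: pd.DataFrame, timepoint: str = ""
) -> ConcentrationResponseDataset:
    """Median-of-ratios size-factor normalization plus log2(x+1).

    Values are divided by the per-sample size factor and
    log2(x+1)-transformed. This is the size-factor core of the standard
    RNA-seq normalization; dispersion modelling is intentionally not
    reproduced here and pre-normalized matrices are accepted upstream.
    """
    counts = raw.to_numpy(dtype=float)
    size_factors = median_of_ratios_size_factors(counts)
    normed = np.log2(counts / size_factors + 1.0)
    df = pd.DataFrame(normed, index=raw.index, columns=raw.columns)
    if not isinstance(df.columns, pd.MultiIndex):
        df.columns = _parse_columns(df.columns)
    return ConcentrationResponseDataset(df, timepoint=timepoint)


def count_responsive_proxy(
    ds: ConcentrationResponseDataset, alpha: float = 0.05
) -> int:
    """Number of genes with one-way ANOVA p < alpha across concentration
    groups — the differential-expression proxy used for timepoint choice."""
    conc = ds.sample_concentrations
    groups = [ds.values.to_numpy()[:, conc == c] for c in ds.concentrations]
    n_hits = 0
    values = ds.values.to_numpy(dtype=float)
    for i in range(values.shape[0]):
        samples = [g[i] for g in groups if g.shape[1] > 0]
        samples = [s for s in samples if len(s) > 0]
        if len(samples) < 2:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.f_oneway(*samples)
        if np.isfinite(p) and p < alpha:
            n_hits += 1
    return n_hits


def select_timepoint(
    datasets: Sequence[ConcentrationResponseDataset], alpha: float = 0.05
) -> ConcentrationResponseDataset:
    """Pick the exposure duration with the most concentration-responsive
    genes (one-way F-test p < alpha per gene); ties go to the earliest
    timepoint in input order."""
    if not datasets:
        raise ValueError("need at least one dataset")
    gene_sets = {tuple(ds.gene_ids) for ds in datasets}
    if len(gene_sets) != 1:
        raise ValueError("datasets must share identical gene ids")
    counts = [count_responsive_proxy(ds, alpha=alpha) for ds in datasets]
    best = int(np.argmax(counts))  # argmax returns first max → earliest wins
    log.info(
        "timepoint selection: responsive-gene counts %s → %s",
        dict(zip([ds.timepoint for ds in datasets], counts)),
        datasets[best].timepoint,
    )
    return datasets[best]


# -- gene sets (GMT) -------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file → {set name: member gene list}."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *members = parts
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = [m for m in members if m]
    return sets


def write_gmt(
    sets: Mapping[str, Sequence[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    lines = []
    for name, members in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


# -- result tables & run summary ------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, **to_csv_kwargs) -> None:
    """Write a result table as CSV with full float precision (re-reading
    reproduces values to stored precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, **to_csv_kwargs)


def write_run_summary(summary: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(summary, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
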