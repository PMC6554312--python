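"""Neutral-locus bookkeeping and mutation-scaled parameter calibration.

Utilities around a coalescent demographic analysis run elsewhere: filtering
putatively neutral loci on genotype missingness before inference, and
converting the sampler's mutation-scaled parameters — population sizes
(theta), divergence times (tau) and migration rates (m) — into natural
units using an assumed per-generation mutation rate and generation time:

    Ne    = theta / (4 mu)
    years = (tau / mu) * generation_time
    total migration probability ~= m * (duration of the migration band)

Defaults are mu = 4.0e-9 per site per generation and a three-year
generation time.  The MCMC itself is out of scope; parameter samples arrive
as a plain numeric table (one row per retained MCMC sample) and are
summarized as means with equal-tailed 95% credible intervals.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "LocusMatrix",
    "CalibrationParams",
    "ScaledEstimate",
    "LocusFilterReport",
    "locus_from_fasta",
    "neutral_locus_filter",
    "missingness_summary",
    "scale_theta_to_Ne",
    "scale_tau_to_years",
    "years_to_tau",
    "total_migration_rate",
    "is_major_band",
    "MAJOR_BAND_THRESHOLD",
    "summarize_trace",
]

MISSING_CHARS = frozenset("?Nn")
MAJOR_BAND_THRESHOLD = 0.05


@dataclass
class LocusMatrix:
    """One locus alignment as per-sample, per-site states.

    ``states`` is an (n_samples, n_sites) array of single characters with
    '?' or 'N' marking a missing genotype (depth below the floor or above
    the per-sample depth ceiling in the upstream calling).
    """

    locus_id: str
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2 or self.states.size == 0:
            raise ValueError(
                f"locus {self.locus_id}: states must be a non-empty 2-D array"
            )

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isin(self.states, list(MISSING_CHARS)).sum())

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.states.size


def locus_from_fasta(path, locus_id: Optional[str] = None) -> LocusMatrix:
    """Load one locus alignment (FASTA, one row per sample)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"{path}: unequal sequence lengths {sorted(lengths)}")
    states = np.array([list(str(r.seq)) for r in records])
    return LocusMatrix(locus_id or Path(path).stem, states)


@dataclass
class LocusFilterReport:
    n_input: int
    n_removed: int
    n_retained: int
    max_missing_fraction: float


def neutral_locus_filter(
    loci: Sequence[LocusMatrix], max_missing_fraction: float = 0.10
) -> tuple[list[LocusMatrix], LocusFilterReport]:
    """Drop loci with *more than* the allowed missing-genotype fraction.

    The boundary is strict: a locus at exactly the threshold is retained.
    """
    if not loci:
        raise ValueError("empty locus list")
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    retained = [
        loc for loc in loci if loc.missing_fraction <= max_missing_fraction
    ]
    report = LocusFilterReport(
        n_input=len(loci),
        n_removed=len(loci) - len(retained),
        n_retained=len(retained),
        max_missing_fraction=max_missing_fraction,
    )
    return retained, report


def missingness_summary(total_sites: int, missing_sites: int) -> float:
    """Percentage of missing sites, rounded half-up to one decimal."""
    if total_sites <= 0:
        raise ValueError("total_sites must be positive")
    if not 0 <= missing_sites <= total_sites:
        raise ValueError("missing_sites outside [0, total_sites]")
    pct = decimal.Decimal(100 * missing_sites) / decimal.Decimal(total_sites)
    return float(pct.quantize(decimal.Decimal("0.1"),
                              rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class CalibrationParams:
    """Mutation rate (per site per generation) and generation time (years)."""

    mu: float = 4.0e-9
    gen_time_years: float = 3.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.gen_time_years <= 0:
            raise ValueError("mu and gen_time_years must be positive")


@dataclass(frozen=True)
class ScaledEstimate:
    """A mutation-scaled value paired with its natural-unit conversion."""

    kind: str  # theta | tau | migration
    raw: float
    natural: float

    def __post_init__(self) -> None:
        if self.kind not in ("theta", "tau", "migration"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.raw < 0 or self.natural < 0:
            raise ValueError("raw and natural must be non-negative")


def scale_theta_to_Ne(theta: float, cal: CalibrationParams) -> float:
    """Effective population size in individuals: Ne = theta / (4 mu)."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return theta / (4.0 * cal.mu)


def scale_tau_to_years(tau: float, cal: CalibrationParams) -> float:
    """Divergence time in years: (tau / mu) generations x generation time."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return tau / cal.mu * cal.gen_time_years


def years_to_tau(years: float, cal: CalibrationParams) -> float:
    """Inverse of :func:`scale_tau_to_years`."""
    return years / cal.gen_time_years * cal.mu


def total_migration_rate(m: float, tau_span: float) -> float:
    """Total migration over a band: rate x duration.

    Approximates the probability that a lineage experienced migration
    through the band during its lifetime.
    """
    if m < 0 or tau_span < 0:
        raise ValueError("m and tau_span must be non-negative")
    return m * tau_span


def is_major_band(total_rate: float) -> bool:
    """Bands with total rate strictly above 0.05 are flagged as major."""
    return total_rate > MAJOR_BAND_THRESHOLD


def summarize_trace(
    samples: pd.DataFrame,
    cal: CalibrationParams,
    kinds: Optional[dict[str, str]] = None,
    band_spans: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Mean and equal-tailed 95% CI per parameter column, raw and natural.

    ``kinds`` maps column name to {"theta", "tau", "migration"}; when
    omitted, columns are classified by prefix ("theta", "tau", "m_").
    Migration columns need the duration of their band in ``band_spans``
    (mutation-scaled, same units as tau) to form total rates; without a
    span the natural columns are left as NaN.
    """
    if samples.empty:
        raise ValueError("empty sample table")
    rows = []
    for col in samples.columns:
        vals = samples[col].to_numpy(dtype=float)
        if kinds and col in kinds:
            kind = kinds[col]
        elif col.startswith("theta"):
            kind = "theta"
        elif col.startswith("tau"):
            kind = "tau"
        elif col.startswith("m_") or col == "m":
            kind = "migration"
        else:
            raise ValueError(f"cannot classify trace column {col!r}")
        mean = float(np.mean(vals))
        lo, hi = np.percentile(vals, [2.5, 97.5])
        if kind == "theta":
            conv = lambda x: scale_theta_to_Ne(x, cal)
        elif kind == "tau":
            conv = lambda x: scale_tau_to_years(x, cal)
        else:
            span = (band_spans or {}).get(col)
            conv = (lambda x: total_migration_rate(x, span)) \
                if span is not None else (lambda x: float("nan"))
        rows.append({
            "parameter": col,
            "kind": kind,
            "mean": mean,
            "ci2.5": float(lo),
            "ci97.5": float(hi),
            "natural_mean": conv(mean),
            "natural_ci2.5": conv(float(lo)),
            "natural_ci97.5": conv(float(hi)),
            "major_band": (
                is_major_band(conv(mean)) if kind == "migration"
                and not np.isnan(conv(mean)) else False
            ),
        })
    return pd.DataFrame(rows)
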