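"""Fertilization accounting and paired nonparametric reporting.

The study design is paired: each subject's semen sample is split and run
through both separation methods (density-gradient centrifugation, DGC, and
the membrane-filter chamber, CA0), so every variable is compared with the
Wilcoxon signed-rank test (two-sided) and described as median ± MAD, with the
MAD unscaled (no 1.4826 normal-consistency factor) — it is a descriptive
spread here, not a σ-estimate.

The exact signed-rank p-value is computed by dynamic programming over the
distribution of the positive-rank sum under sign exchangeability, which is
identical to full 2ⁿ sign enumeration but O(n·Σr). Zero differences are
discarded before ranking (the textbook procedure); ties get midranks, and the
large-sample branch uses the tie-corrected variance with a 0.5 continuity
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class CycleRecord:
    """One ART cycle's oocyte accounting for one separation method."""

    cycle_id: str
    method: Literal["DGC", "CA0"]
    art: Literal["IVF", "ICSI"]
    n_mii_inseminated: int
    n_2pn2pb: int  # normally fertilized: 2 pronuclei + 2 polar bodies
    n_3pn2pb: int = 0  # triploid, discarded from culture
    n_unfertilized: int = 0
    n_degenerated: int = 0  # post-ICSI degenerated oocytes

    def __post_init__(self) -> None:
        counts = (
            self.n_mii_inseminated, self.n_2pn2pb, self.n_3pn2pb,
            self.n_unfertilized, self.n_degenerated,
        )
        if any(c < 0 for c in counts):
            raise ValueError("oocyte counts must be non-negative")
        if (self.n_2pn2pb + self.n_3pn2pb + self.n_unfertilized
                + self.n_degenerated) > self.n_mii_inseminated:
            raise ValueError("outcome counts exceed inseminated oocytes")


@dataclass(frozen=True)
class PairedCohort:
    """Per-subject paired (DGC, CA0) measurements of one variable."""

    variable: str
    units: str
    sample_class: Literal["Nz", "Tz"]
    subject_id: tuple[str, ...]
    dgc: np.ndarray
    ca0: np.ndarray
    group: str = "other"  # report grouping: counts | motility | em | calcium | fertilization

    def __post_init__(self) -> None:
        d = np.asarray(self.dgc, dtype=float)
        c = np.asarray(self.ca0, dtype=float)
        object.__setattr__(self, "dgc", d)
        object.__setattr__(self, "ca0", c)
        object.__setattr__(self, "subject_id", tuple(self.subject_id))
        if not (len(self.subject_id) == d.size == c.size):
            raise ValueError("subject_id, dgc, ca0 must be equal length")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    def complete(self) -> "PairedCohort":
        """Drop incomplete pairs (NaN in either arm); the drop count is logged."""
        ok = np.isfinite(self.dgc) & np.isfinite(self.ca0)
        if not ok.all():
            logger.info(
                "%s/%s: excluded %d incomplete pair(s)",
                self.sample_class, self.variable, int((~ok).sum()),
            )
        return PairedCohort(
            variable=self.variable, units=self.units,
            sample_class=self.sample_class,
            subject_id=tuple(np.asarray(self.subject_id)[ok]),
            dgc=self.dgc[ok], ca0=self.ca0[ok], group=self.group,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": list(self.subject_id),
                "sample_class": self.sample_class,
                "variable": self.variable,
                "units": self.units,
                "dgc_value": self.dgc,
                "ca0_value": self.ca0,
            }
        )


@dataclass(frozen=True)
class MedianMad:
    median: float
    mad: float  # unscaled median absolute deviation
    n: int


@dataclass(frozen=True)
class WilcoxonResult:
    n_used: int  # non-zero differences
    statistic_w: float  # sum of positive-difference ranks
    p_two_sided: float
    mode: Literal["exact", "normal_approx", "degenerate"]


def fertilization_rate(record: CycleRecord) -> float:
    """Fertilization rate in %: zygotes (2PN+2PB) over MII oocytes inseminated.

    Triploid (3PN) and degenerated oocytes stay in the denominator — they were
    inseminated — but never count as zygotes.
    """
    if record.n_mii_inseminated < 1:
        raise ValueError("no inseminated MII oocytes: rate undefined")
    return 100.0 * record.n_2pn2pb / record.n_mii_inseminated


def median_mad(values: Sequence[float]) -> MedianMad:
    """Median and unscaled MAD of finite values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("median_mad needs at least one finite value")
    med = float(np.median(v))
    return MedianMad(median=med, mad=float(np.median(np.abs(v - med))), n=int(v.size))


def _exact_sf_cdf(ranks: np.ndarray, w: float) -> tuple[float, float]:
    """(P[W >= w], P[W <= w]) under random signs, by generating-function DP.

    Midranks are half-integers, so doubling makes every rank an exact integer
    and the DP exact.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w))
    sf = float(counts[w2:].sum())
    cdf = float(counts[: w2 + 1].sum())
    return sf, cdf


def signed_rank_test(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 20
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples ``x`` vs ``y``.

    Differences ``x − y`` equal to zero are discarded; with every difference
    zero the test is degenerate and reported as p = 1. Up to ``exact_limit``
    non-zero differences the p-value is exact (sign-enumeration distribution);
    beyond that, a normal approximation with tie-corrected variance and
    continuity correction is used. The two-sided p is ``min(1, 2 × smaller
    one-sided tail)``.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("paired values must be finite")
    d = d[d != 0]
    n = int(d.size)
    if n == 0:
        return WilcoxonResult(n_used=0, statistic_w=0.0, p_two_sided=1.0,
                              mode="degenerate")
    ranks = stats.rankdata(np.abs(d))  # midranks for ties
    w = float(ranks[d > 0].sum())
    if n <= exact_limit:
        sf, cdf = _exact_sf_cdf(ranks, w)
        p = min(1.0, 2.0 * min(sf, cdf))
        return WilcoxonResult(n_used=n, statistic_w=w, p_two_sided=p, mode="exact")
    mu = n * (n + 1) / 4.0
    sigma = float(np.sqrt(np.sum(ranks**2) / 4.0))  # tie-corrected via midranks
    if sigma == 0:
        return WilcoxonResult(n_used=n, statistic_w=w, p_two_sided=1.0,
                              mode="degenerate")
    z = (abs(w - mu) - 0.5) / sigma
    p = min(1.0, 2.0 * float(stats.norm.sf(max(z, 0.0))))
    return WilcoxonResult(n_used=n, statistic_w=w, p_two_sided=p,
                          mode="normal_approx")


def wilcoxon_paired(cohort: PairedCohort, exact_limit: int = 20) -> WilcoxonResult:
    """Signed-rank test of a paired cohort (DGC minus CA0 differences)."""
    c = cohort.complete()
    if c.n_subjects == 0:
        raise ValueError("no complete pairs")
    return signed_rank_test(c.dgc, c.ca0, exact_limit=exact_limit)


def significance_tier(
    p: float, levels: Sequence[float] = SIGNIFICANCE_LEVELS
) -> str:
    """Significance label at the reporting thresholds (NS above all of them)."""
    tier = "NS"
    for lev in sorted(levels, reverse=True):
        if p <= lev:
            tier = f"P<={lev:g}"
    return tier


def cycles_to_cohort(
    cycles: Iterable[CycleRecord], art: str, sample_class: str = "Tz"
) -> PairedCohort:
    """Pair per-cycle fertilization rates across methods for one ART.

    Cycles are matched by ``cycle_id``; only cycles with both arms enter.
    """
    rates: dict[str, dict[str, float]] = {}
    for rec in cycles:
        if rec.art != art:
            continue
        rates.setdefault(rec.cycle_id, {})[rec.method] = fertilization_rate(rec)
    ids = sorted(cid for cid, arms in rates.items() if {"DGC", "CA0"} <= arms.keys())
    if not ids:
        raise ValueError(f"no complete {art} cycles")
    return PairedCohort(
        variable=f"fertilization_rate_{art.lower()}", units="%",
        sample_class=sample_class, subject_id=tuple(ids),
        dgc=[rates[i]["DGC"] for i in ids], ca0=[rates[i]["CA0"] for i in ids],
        group="fertilization",
    )


def build_report(
    cohorts: Sequence[PairedCohort],
    cycles: Sequence[CycleRecord] = (),
    alpha_levels: Sequence[float] = SIGNIFICANCE_LEVELS,
    exact_limit: int = 20,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Median ± MAD per arm, Wilcoxon p and significance tier, per variable.

    Returns a ``summary`` table plus one supplement-shaped table per variable
    group (counts+motility, Em, Ca²⁺ kinetics, fertilization). When ``cycles``
    are given, per-cycle fertilization rates are paired across methods and
    appended; with no cycles the fertilization section is omitted (logged).
    No multiple-testing adjustment is applied: p-values are per-variable, as
    is conventional for this descriptive comparison (flagged in the output).
    """
    cohorts = list(cohorts)
    if cycles:
        for art in ("IVF", "ICSI"):
            try:
                cohorts.append(cycles_to_cohort(cycles, art))
            except ValueError:
                logger.info("no complete %s cycles; section omitted", art)
    else:
        logger.info("no ART cycles provided; fertilization section omitted")

    rows = []
    for cohort in cohorts:
        c = cohort.complete()
        mm_d = median_mad(c.dgc)
        mm_c = median_mad(c.ca0)
        wres = wilcoxon_paired(c, exact_limit=exact_limit)
        rows.append(
            {
                "sample_class": c.sample_class,
                "group": c.group,
                "variable": c.variable,
                "units": c.units,
                "n_pairs": c.n_subjects,
                "dgc_median": mm_d.median,
                "dgc_mad": mm_d.mad,
                "ca0_median": mm_c.median,
                "ca0_mad": mm_c.mad,
                "wilcoxon_w": wres.statistic_w,
                "n_used": wres.n_used,
                "p_two_sided": wres.p_two_sided,
                "p_mode": wres.mode,
                "significance": significance_tier(wres.p_two_sided, alpha_levels),
            }
        )
    summary = pd.DataFrame(rows)
    tables: dict[str, pd.DataFrame] = {"summary": summary}
    group_files = {
        "table_counts_motility": ("counts", "motility"),
        "table_em": ("em",),
        "table_calcium": ("calcium",),
        "table_fertilization": ("fertilization",),
    }
    for name, groups in group_files.items():
        sub = summary[summary["group"].isin(groups)]
        if not sub.empty:
            tables[name] = sub.reset_index(drop=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "NOTES.txt").write_text(
            "p-values are per-variable, two-sided Wilcoxon signed-rank, "
            "unadjusted for multiple testing.\n"
        )
    return tables
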