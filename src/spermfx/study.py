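"""Study-level constants and synthetic-study assembly.

``COHORT_TARGETS`` holds the per-variable paired medians ± MADs of the DGC
vs CA0 comparison in normozoospermic (Nz) and teratozoospermic (Tz) samples,
together with each variable's reported pair count. These values define the
conditions the synthetic study emulates; the generator is calibrated so a
generated cohort's sample medians equal them. The sperm-count MADs are not
reported numerically anywhere and default to 25% of the median.

Tables written from these cohorts are synthetic stand-ins for the study's
supplementary data and are labelled as such in their filenames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .outcome_stats import PairedCohort
from .synthetic_data import CohortSpec, make_cohort

#: median semen counts (×10⁶) before separation, per sample class
SEMEN_COUNT_MEDIANS = {"Nz": 205.0, "Tz": 74.5}


@dataclass(frozen=True)
class CohortTarget:
    sample_class: str
    group: str
    variable: str
    units: str
    n: int
    dgc: tuple[float, float]  # (median, MAD)
    ca0: tuple[float, float]


COHORT_TARGETS: tuple[CohortTarget, ...] = (
    # recovered sperm counts, ×10⁶ (count MADs unreported: 25% of median)
    CohortTarget("Nz", "counts", "sperm_count", "1e6 cells", 12, (36.0, 9.0), (52.0, 13.0)),
    CohortTarget("Tz", "counts", "sperm_count", "1e6 cells", 36, (4.8, 1.2), (9.2, 2.3)),
    # motility class percentages
    CohortTarget("Nz", "motility", "pct_progressive", "%", 9, (79.0, 6.0), (88.0, 3.0)),
    CohortTarget("Nz", "motility", "pct_non_progressive", "%", 9, (13.0, 2.0), (11.0, 5.0)),
    CohortTarget("Nz", "motility", "pct_immotile", "%", 9, (8.0, 4.0), (4.0, 3.0)),
    CohortTarget("Tz", "motility", "pct_progressive", "%", 46, (85.0, 2.0), (84.0, 3.0)),
    CohortTarget("Tz", "motility", "pct_non_progressive", "%", 46, (13.0, 2.0), (13.0, 3.0)),
    CohortTarget("Tz", "motility", "pct_immotile", "%", 46, (2.0, 1.0), (3.0, 1.0)),
    # resting membrane potential, mV
    CohortTarget("Nz", "em", "resting_em", "mV", 11, (-48.8, 8.1), (-44.0, 10.4)),
    CohortTarget("Tz", "em", "resting_em", "mV", 22, (-78.9, 8.1), (-66.8, 8.6)),
    # progesterone-induced Ca²⁺ transient descriptors
    CohortTarget("Nz", "calcium", "delta_p4", "fold over basal", 9, (1.9, 0.2), (1.1, 0.1)),
    CohortTarget("Nz", "calcium", "tau_up", "s", 9, (3.3, 1.1), (2.7, 0.5)),
    CohortTarget("Nz", "calcium", "tau_down", "s", 9, (17.7, 4.7), (13.2, 4.9)),
    CohortTarget("Tz", "calcium", "delta_p4", "fold over basal", 46, (2.5, 0.1), (1.6, 0.2)),
    CohortTarget("Tz", "calcium", "tau_up", "s", 46, (7.6, 3.9), (7.0, 3.5)),
    CohortTarget("Tz", "calcium", "tau_down", "s", 46, (23.5, 8.8), (26.7, 6.7)),
    # fertilization rates, % (Tz patients only)
    CohortTarget("Tz", "fertilization", "fertilization_rate_ivf", "%", 72, (71.4, 21.4), (66.6, 16.6)),
    CohortTarget("Tz", "fertilization", "fertilization_rate_icsi", "%", 22, (70.1, 10.8), (82.7, 17.4)),
)

#: latent arm-arm correlation of the paired design (see docs/methods.md)
DEFAULT_ARM_CORRELATION = 0.6


def target_spec(
    target: CohortTarget, seed: int, calibrate_median: bool = True
) -> CohortSpec:
    return CohortSpec(
        n_subjects=target.n,
        sample_class=target.sample_class,
        variable=target.variable,
        units=target.units,
        dgc_median=target.dgc[0],
        dgc_mad=target.dgc[1],
        ca0_median=target.ca0[0],
        ca0_mad=target.ca0[1],
        correlation=DEFAULT_ARM_CORRELATION,
        seed=seed,
        group=target.group,
        calibrate_median=calibrate_median,
    )


def build_study_cohorts(
    seed: int = 0,
    calibrate_median: bool = True,
    targets: Sequence[CohortTarget] = COHORT_TARGETS,
) -> list[PairedCohort]:
    """One synthetic paired cohort per study variable.

    Per-cohort seeds are spawned from ``seed`` so each variable's draw is
    independent but the whole study is reproducible from one integer.
    """
    seeds = np.random.SeedSequence(seed).generate_state(len(targets))
    return [
        make_cohort(target_spec(t, int(s) % (2**31), calibrate_median))
        for t, s in zip(targets, seeds)
    ]


def find_cohort(
    cohorts: Sequence[PairedCohort], sample_class: str, variable: str
) -> PairedCohort:
    for c in cohorts:
        if c.sample_class == sample_class and c.variable == variable:
            return c
    raise KeyError(f"no cohort {sample_class}/{variable}")


def write_supplement_tables(
    cohorts: Sequence[PairedCohort], out_dir: str | Path
) -> list[Path]:
    """Write supplement-shaped per-subject tables (synthetic stand-ins)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = {
        "counts_motility": ("counts", "motility"),
        "em": ("em",),
        "calcium": ("calcium",),
        "fertilization": ("fertilization",),
    }
    paths = []
    for name, grp in groups.items():
        subset = [c for c in cohorts if c.group in grp]
        if not subset:
            continue
        import pandas as pd

        df = pd.concat([c.to_frame() for c in subset], ignore_index=True)
        path = out / f"synthetic_table_{name}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    return paths
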