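"""End-to-end synthetic study: simulate → analyze → report.

``run_study`` generates a full paired study at the target medians, pushes
every fluorescence trace through the estimators it was generated for
(membrane-potential calibration, Ca²⁺ kinetics), runs the CASA stage on
generated tracks, and builds the paired report plus a provenance manifest.
Deterministic and byte-identical for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calcium_kinetics import extract_kinetics, normalize_trace
from .em_calibration import NernstParams, estimate_resting_em
from .errors import SpermfxError
from .motility_kinematics import CasaConfig, analyze_tracks
from .outcome_stats import PairedCohort, build_report
from .study import COHORT_TARGETS, build_study_cohorts, find_cohort
from .synthetic_data import (
    CalTraceTruth,
    P4TraceTruth,
    TrackSpec,
    calibration_trace_spec,
    make_calibration_trace,
    make_p4_trace,
    make_tracks,
    p4_trace_spec,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one reproducible study run."""

    seed: int = 42
    out_dir: str = "results/demo"
    # membrane-potential stage
    em_window: float = 5.0  # s, trailing plateau window
    em_temperature: float = 310.15  # K
    em_intracellular_k: float = 120.0  # mM
    em_trace_noise_sd: float = 1.0  # a.u. (≈2% of the calibration span)
    em_slope: float = 1.0  # a.u.·mV⁻¹, true dye slope of generated traces
    # Ca²⁺ stage
    ca_smooth_window: int = 5  # samples
    ca_noise_frac: float = 0.03  # noise sd as a fraction of transient amplitude
    ca_sampling_rate: float = 10.0  # Hz
    # CASA stage
    casa: CasaConfig = field(default_factory=CasaConfig)
    casa_n_tracks: int = 300
    # statistics
    stats_exact_limit: int = 20


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _measure_em_cohorts(
    truth_cohorts: list[PairedCohort], config: RunConfig, rng: np.random.Generator
) -> list[PairedCohort]:
    """Round-trip every subject's Em through a noisy calibration trace."""
    params = NernstParams(
        temperature=config.em_temperature, intracellular_k=config.em_intracellular_k
    )
    out = []
    for cohort in truth_cohorts:
        measured = {}
        for arm_name, arm in (("dgc", cohort.dgc), ("ca0", cohort.ca0)):
            est = []
            for em_true in arm:
                truth = CalTraceTruth(
                    resting_em=float(em_true),
                    fluorescence_per_mv=config.em_slope,
                    intracellular_k=config.em_intracellular_k,
                    temperature=config.em_temperature,
                )
                spec = calibration_trace_spec(
                    truth, noise_sd=config.em_trace_noise_sd
                )
                trace = make_calibration_trace(
                    truth, spec, seed=int(rng.integers(2**31))
                )
                cal = estimate_resting_em(trace, params, window=config.em_window)
                est.append(cal.resting_em)
            measured[arm_name] = np.array(est)
        out.append(
            PairedCohort(
                variable=cohort.variable, units=cohort.units,
                sample_class=cohort.sample_class, subject_id=cohort.subject_id,
                dgc=measured["dgc"], ca0=measured["ca0"], group=cohort.group,
            )
        )
    return out


def _measure_ca_cohorts(
    delta: PairedCohort, tau_up: PairedCohort, tau_down: PairedCohort,
    config: RunConfig, rng: np.random.Generator,
) -> list[PairedCohort]:
    """Round-trip every subject's transient through a noisy Fluo-3 trace."""
    baseline, mn_level = 100.0, 40.0
    measured = {"delta_p4": {}, "tau_up": {}, "tau_down": {}}
    for arm_name in ("dgc", "ca0"):
        d_arr = getattr(delta, arm_name)
        u_arr = getattr(tau_up, arm_name)
        w_arr = getattr(tau_down, arm_name)
        est = {"delta_p4": [], "tau_up": [], "tau_down": []}
        for d, u, w in zip(d_arr, u_arr, w_arr):
            p4_time = 10.0
            iono_time = p4_time + 2 * u + max(3 * w, 5.0)
            # acquisition adapts to the kinetics: fast transients need a
            # finer sampling rate to keep half-times resolvable
            rate = max(config.ca_sampling_rate, 2.5 / min(u, w))
            truth = P4TraceTruth(
                delta_p4=float(d), tau_up=float(u), tau_down=float(w),
                iono_level=baseline + 1.3 * d * (baseline - mn_level),
                mn_level=mn_level, p4_time=p4_time, iono_time=iono_time,
                mn_time=iono_time + 8.0,
            )
            amplitude = d * (baseline - mn_level)
            spec = p4_trace_spec(
                truth, baseline_fluorescence=baseline,
                noise_sd=config.ca_noise_frac * amplitude,
                sampling_rate=rate,
            )
            trace = make_p4_trace(truth, spec, seed=int(rng.integers(2**31)))
            kin = extract_kinetics(
                normalize_trace(trace), smooth_window=config.ca_smooth_window
            )
            est["delta_p4"].append(kin.delta_p4)
            est["tau_up"].append(np.nan if kin.tau_up is None else kin.tau_up)
            est["tau_down"].append(np.nan if kin.tau_down is None else kin.tau_down)
        for var in measured:
            measured[var][arm_name] = np.array(est[var])
    out = []
    for var, template in (
        ("delta_p4", delta), ("tau_up", tau_up), ("tau_down", tau_down)
    ):
        out.append(
            PairedCohort(
                variable=template.variable, units=template.units,
                sample_class=template.sample_class, subject_id=template.subject_id,
                dgc=measured[var]["dgc"], ca0=measured[var]["ca0"],
                group=template.group,
            )
        )
    return out


def _casa_profiles(config: RunConfig, cohorts: list[PairedCohort],
                   rng: np.random.Generator) -> pd.DataFrame:
    """Representative per-sample CASA runs at each class's median motility mix."""
    rows = []
    for sample_class in ("Nz", "Tz"):
        mix_vars = ("pct_progressive", "pct_non_progressive", "pct_immotile")
        for arm in ("dgc", "ca0"):
            med = {
                v: float(np.median(getattr(find_cohort(cohorts, sample_class, v), arm)))
                for v in mix_vars
            }
            total = sum(med.values())
            spec = TrackSpec(
                n_tracks=config.casa_n_tracks,
                class_mix={
                    "progressive": med["pct_progressive"] / total,
                    "non_progressive": med["pct_non_progressive"] / total,
                    "immotile": med["pct_immotile"] / total,
                },
            )
            tracks = make_tracks(spec, seed=int(rng.integers(2**31)))
            _, profile = analyze_tracks(tracks, config.casa)
            rows.append(
                {
                    "sample_class": sample_class,
                    "method": {"dgc": "DGC", "ca0": "CA0"}[arm],
                    "n_tracks": profile.n_tracks,
                    "pct_progressive": profile.pct_progressive,
                    "pct_non_progressive": profile.pct_non_progressive,
                    "pct_immotile": profile.pct_immotile,
                    "n_unanalyzed": profile.n_unanalyzed,
                }
            )
    return pd.DataFrame(rows)


def run_study(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full synthetic study and write report tables plus a manifest.

    Stages: (1) draw paired cohorts at the target medians; (2) regenerate and
    re-estimate every subject's membrane potential and Ca²⁺ transient from
    synthetic traces, so the reported Em/Ca medians are measured, not copied;
    (3) run the CASA stage on generated tracks; (4) paired median ± MAD /
    Wilcoxon report. Any stage failure aborts with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    stage = "simulate-cohorts"
    try:
        truth_cohorts = build_study_cohorts(seed=config.seed, calibrate_median=True)

        stage = "membrane-potential"
        em_truth = [c for c in truth_cohorts if c.group == "em"]
        em_measured = _measure_em_cohorts(em_truth, config, rng)

        stage = "calcium-kinetics"
        ca_measured = []
        for sample_class in ("Nz", "Tz"):
            ca_measured.extend(
                _measure_ca_cohorts(
                    find_cohort(truth_cohorts, sample_class, "delta_p4"),
                    find_cohort(truth_cohorts, sample_class, "tau_up"),
                    find_cohort(truth_cohorts, sample_class, "tau_down"),
                    config, rng,
                )
            )

        stage = "casa"
        casa_table = _casa_profiles(config, truth_cohorts, rng)

        stage = "report"
        direct = [c for c in truth_cohorts if c.group in ("counts", "motility", "fertilization")]
        tables = build_report(
            direct + em_measured + ca_measured,
            exact_limit=config.stats_exact_limit,
            out_dir=out_dir,
        )
        casa_table.to_csv(out_dir / "casa_profiles.csv", index=False)
        tables["casa_profiles"] = casa_table
    except SpermfxError as exc:
        raise SpermfxError(f"stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    cfg = asdict(config)
    cfg["casa"] = asdict(config.casa)
    cfg.pop("out_dir")  # manifest is independent of where it is written
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    outputs = sorted(p for p in out_dir.iterdir() if p.name != "manifest.json")
    manifest = {
        "spermfx_version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": config_hash,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("study complete: %d tables under %s", len(outputs), out_dir)
    return tables
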