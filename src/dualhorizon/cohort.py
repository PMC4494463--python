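"""Cohort simulation: a small sample of subjects, one torted eye each.

Emulates the study design the simulator targets: N subjects (default 9),
each with one cyclodeviated ("affected") eye whose torsion is drawn uniformly
over a clinical range (default -2.5 to +2.0 deg) and an untorted fellow eye.
Horizontal and vertical discrimination thresholds are measured per eye,
either with the simulated 4-2-1 staircase or with the analytic oracle, and
the association between torsion and the affected-eye horizontal threshold is
quantified with a Pearson correlation (two-sided p from the exact t
transform on n-2 degrees of freedom). The fellow-eye correlation is computed
the same way and serves as the built-in null comparison.

Seeding: a master seed fans out deterministically to per-(subject, eye, axis)
streams via ``np.random.default_rng([master, subject_index, eye_code,
axis_code])``, so any single staircase is replayable in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .encoding import get_calibration
from .errors import CohortTooSmallError, ConfigurationError, UndefinedCorrelationError
from .observer import ObserverParams, analytic_threshold
from .staircase import StaircaseConfig, run_staircase
from .stimuli import DEFAULT_N_DETECTORS, DEFAULT_SIZE_ARCMIN
from .torsion import TorsionState

logger = logging.getLogger("dualhorizon")

DEFAULT_N_SUBJECTS = 9
DEFAULT_TORSION_RANGE = (-2.5, 2.0)

_EYE_CODE = {"affected": 0, "fellow": 1}
_AXIS_CODE = {"horizontal": 0, "vertical": 1}


@dataclass(frozen=True)
class ObserverSpread:
    """Between-subject jitter (SD, IR %) on the observer parameters.

    Sampled additively around the base observer and truncated below at
    ``floor`` so noise and criterion stay physiologically positive.
    """

    sigma_sd: float = 0.2
    criterion_sd: float = 0.2
    floor: float = 0.5


@dataclass(frozen=True)
class Subject:
    """One simulated participant: a torted eye, an untorted fellow eye."""

    subject_id: int
    lambda_affected: float
    observer: ObserverParams
    lambda_fellow: float = 0.0


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class CohortResult:
    """Per-record thresholds and the two torsion-threshold correlations."""

    records: pd.DataFrame
    correlation_affected: CorrelationResult
    correlation_fellow: CorrelationResult
    n_excluded: int = 0
    trial_logs: pd.DataFrame | None = None


def generate_cohort(
    n: int = DEFAULT_N_SUBJECTS,
    torsion_range: tuple[float, float] = DEFAULT_TORSION_RANGE,
    observer_spread: ObserverSpread = ObserverSpread(),
    seed: int = 0,
    base_observer: ObserverParams = ObserverParams(),
) -> list[Subject]:
    """Draw a cohort: uniform torsions, jittered observer parameters.

    Raises
    ------
    CohortTooSmallError
        If ``n < 3`` (the correlation would be undefined or degenerate).
    """
    if n < 3:
        raise CohortTooSmallError(f"need at least 3 subjects, got {n}")
    lo, hi = torsion_range
    if lo > hi:
        raise ConfigurationError(f"torsion_range must be ordered, got {torsion_range}")
    rng = np.random.default_rng([int(seed), 0])
    lambdas = rng.uniform(lo, hi, size=n)
    subjects = []
    for i in range(n):
        sigma = max(
            observer_spread.floor,
            base_observer.sigma + observer_spread.sigma_sd * rng.standard_normal(),
        )
        criterion = max(
            observer_spread.floor,
            base_observer.criterion
            + observer_spread.criterion_sd * rng.standard_normal(),
        )
        subjects.append(
            Subject(
                subject_id=i,
                lambda_affected=float(lambdas[i]),
                observer=ObserverParams(
                    sigma=sigma,
                    criterion=criterion,
                    gain=base_observer.gain,
                    lapse_rate=base_observer.lapse_rate,
                ),
            )
        )
    return subjects


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with the exact small-sample p-value.

    Raises
    ------
    UndefinedCorrelationError
        If either input is constant (zero variance) or the lengths differ
        or fall below 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise UndefinedCorrelationError(
            f"need two equal-length 1-D arrays of size >= 3, got {x.shape}, {y.shape}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    res = scipy.stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)


def measure_cohort(
    cohort: list[Subject],
    staircase_config: StaircaseConfig = StaircaseConfig(),
    mode: str = "staircase",
    seed: int = 0,
    p_target: float = 0.5,
    use_abs_torsion: bool = False,
    size: float = DEFAULT_SIZE_ARCMIN,
    n_detectors: int = DEFAULT_N_DETECTORS,
    keep_trial_logs: bool = False,
) -> CohortResult:
    """Measure both axes of both eyes of every subject; correlate.

    ``mode="staircase"`` runs the simulated 4-2-1 procedure per record;
    ``mode="analytic"`` evaluates the closed-form oracle (no trial noise).
    The primary association is affected-eye torsion vs affected-eye
    horizontal threshold; the fellow-eye association (same torsions vs
    fellow-eye horizontal thresholds, measured at lambda = 0) is the null
    comparison. Non-converged staircases are excluded from the correlations
    with a logged count.
    """
    if mode not in ("staircase", "analytic"):
        raise ConfigurationError(f"mode must be 'staircase' or 'analytic', got {mode!r}")
    calib = get_calibration(size=size, n_detectors=n_detectors)
    rows = []
    logs = []
    for subject in cohort:
        for eye, lam in (
            ("affected", subject.lambda_affected),
            ("fellow", subject.lambda_fellow),
        ):
            torsion = TorsionState(lam, gain=subject.observer.gain)
            for axis in ("horizontal", "vertical"):
                row = {
                    "subject_id": subject.subject_id,
                    "eye": eye,
                    "axis": axis,
                    "lambda_deg": lam,
                    "mode": mode,
                }
                if mode == "analytic":
                    row["ir_threshold"] = analytic_threshold(
                        axis, torsion, subject.observer, p_target=p_target, calib=calib
                    )
                    row["n_trials"] = 0
                    row["converged"] = True
                else:
                    rng = np.random.default_rng(
                        [int(seed), subject.subject_id, _EYE_CODE[eye], _AXIS_CODE[axis]]
                    )
                    est = run_staircase(
                        axis,
                        torsion,
                        subject.observer,
                        config=staircase_config,
                        noise_source=rng,
                        calib=calib,
                    )
                    row["ir_threshold"] = est.ir_threshold
                    row["n_trials"] = est.n_trials
                    row["converged"] = est.converged
                    if keep_trial_logs and est.trial_log is not None:
                        log = est.trial_log.copy()
                        log.insert(0, "subject_id", subject.subject_id)
                        log.insert(1, "eye", eye)
                        logs.append(log)
                rows.append(row)
    records = pd.DataFrame(rows)

    def _corr(eye: str) -> tuple[CorrelationResult, int]:
        sel = records[
            (records.eye == eye)
            & (records.axis == "horizontal")
            & records.converged
        ]
        excluded = int(
            ((records.eye == eye) & (records.axis == "horizontal")).sum() - len(sel)
        )
        lambdas = [
            s.lambda_affected for s in cohort if s.subject_id in set(sel.subject_id)
        ]
        x = np.abs(lambdas) if use_abs_torsion else np.asarray(lambdas)
        try:
            return pearson(x, sel.ir_threshold.to_numpy()), excluded
        except UndefinedCorrelationError:
            # e.g. identical fellow-eye thresholds when observer jitter is off
            logger.warning("degenerate %s-eye correlation (constant input)", eye)
            return CorrelationResult(r=float("nan"), p=float("nan"), n=len(sel)), excluded

    corr_aff, excl_a = _corr("affected")
    corr_fel, excl_f = _corr("fellow")
    n_excluded = excl_a + excl_f
    if n_excluded:
        logger.warning("excluded %d non-converged records from correlations", n_excluded)
    return CohortResult(
        records=records,
        correlation_affected=corr_aff,
        correlation_fellow=corr_fel,
        n_excluded=n_excluded,
        trial_logs=pd.concat(logs, ignore_index=True) if logs else None,
    )


# ---------------------------------------------------------------------------
# End-to-end experiment driver
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "mode": "staircase",
    "n_subjects": DEFAULT_N_SUBJECTS,
    "torsion_range": list(DEFAULT_TORSION_RANGE),
    "use_abs_torsion": False,
    "p_target": 0.5,
    "observer": {"sigma": 2.0, "criterion": 3.0, "gain": 0.0017, "lapse_rate": 0.0},
    "spread": {"sigma_sd": 0.2, "criterion_sd": 0.2},
    "stimulus": {"size": DEFAULT_SIZE_ARCMIN, "n_detectors": DEFAULT_N_DETECTORS},
    "staircase": {
        "start_ir": 12.0,
        "step_sequence": [4.0, 2.0, 1.0],
        "reversals_per_step": 2,
        "total_reversals": 16,
        "max_trials": 120,
        "reversal_average_count": 10,
    },
    "out_dir": "results",
}

_NUMERIC = (int, float)


def _validate(cfg: dict) -> None:
    def fail(path: str, msg: str):
        raise ConfigurationError(f"config field '{path}': {msg}")

    if cfg["mode"] not in ("staircase", "analytic"):
        fail("mode", f"must be 'staircase' or 'analytic', got {cfg['mode']!r}")
    if not isinstance(cfg["n_subjects"], int) or cfg["n_subjects"] < 3:
        fail("n_subjects", f"must be an integer >= 3, got {cfg['n_subjects']!r}")
    tr = cfg["torsion_range"]
    if (
        not isinstance(tr, (list, tuple))
        or len(tr) != 2
        or not all(isinstance(v, _NUMERIC) for v in tr)
        or tr[0] > tr[1]
    ):
        fail("torsion_range", f"must be an ordered [lo, hi] pair, got {tr!r}")
    if not 0 < cfg["p_target"] < 1:
        fail("p_target", f"must be in (0, 1), got {cfg['p_target']!r}")
    for grp, keys in (
        ("observer", ("sigma", "criterion", "gain", "lapse_rate")),
        ("spread", ("sigma_sd", "criterion_sd")),
        ("stimulus", ("size", "n_detectors")),
    ):
        for k in keys:
            v = cfg[grp][k]
            if not isinstance(v, _NUMERIC) or v < 0:
                fail(f"{grp}.{k}", f"must be a non-negative number, got {v!r}")


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigurationError(f"config field '{where}': unknown field")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(f"config field '{where}': expected a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults <- YAML/JSON file <- explicit overrides, then validate."""
    import yaml

    cfg = DEFAULT_CONFIG
    if path is not None:
        try:
            with open(path) as fh:
                user = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
        if user is None:
            user = {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"config {path} must be a mapping at top level")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    _validate(cfg)
    return cfg


def run_experiment(
    config: str | Path | dict | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """End-to-end driver: generate, measure, correlate, write result files.

    ``config`` may be a YAML/JSON path, a dict of overrides, or None for the
    defaults. Writes ``cohort.csv``, ``thresholds.csv``, ``trials.csv``
    (staircase mode) and ``summary.json`` under ``out_dir`` and returns the
    summary dict (which includes the file paths).
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(path=config)
    else:
        cfg = load_config(overrides=config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)

    obs = cfg["observer"]
    base_observer = ObserverParams(
        sigma=obs["sigma"],
        criterion=obs["criterion"],
        gain=obs["gain"],
        lapse_rate=obs["lapse_rate"],
    )
    spread = ObserverSpread(
        sigma_sd=cfg["spread"]["sigma_sd"], criterion_sd=cfg["spread"]["criterion_sd"]
    )
    sc = cfg["staircase"]
    staircase_config = StaircaseConfig(
        start_ir=sc["start_ir"],
        step_sequence=tuple(sc["step_sequence"]),
        reversals_per_step=sc["reversals_per_step"],
        total_reversals=sc["total_reversals"],
        max_trials=sc["max_trials"],
        reversal_average_count=sc["reversal_average_count"],
    )

    logger.info(
        "running experiment: mode=%s n=%d seed=%d",
        cfg["mode"], cfg["n_subjects"], cfg["seed"],
    )
    cohort = generate_cohort(
        n=cfg["n_subjects"],
        torsion_range=tuple(cfg["torsion_range"]),
        observer_spread=spread,
        seed=cfg["seed"],
        base_observer=base_observer,
    )
    result = measure_cohort(
        cohort,
        staircase_config=staircase_config,
        mode=cfg["mode"],
        seed=cfg["seed"],
        p_target=cfg["p_target"],
        use_abs_torsion=cfg["use_abs_torsion"],
        size=cfg["stimulus"]["size"],
        n_detectors=int(cfg["stimulus"]["n_detectors"]),
        keep_trial_logs=cfg["mode"] == "staircase",
    )

    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    cohort_frame = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "lambda_deg": s.lambda_affected,
                "lambda_fellow": s.lambda_fellow,
                "sigma": s.observer.sigma,
                "criterion": s.observer.criterion,
                "gain": s.observer.gain,
            }
            for s in cohort
        ]
    )
    paths = {
        "cohort": str(out / "cohort.csv"),
        "thresholds": str(out / "thresholds.csv"),
        "summary": str(out / "summary.json"),
    }
    cohort_frame.to_csv(paths["cohort"], index=False)
    result.records.to_csv(paths["thresholds"], index=False)
    if result.trial_logs is not None:
        paths["trials"] = str(out / "trials.csv")
        result.trial_logs.to_csv(paths["trials"], index=False)

    summary = {
        "config": cfg,
        "correlation_affected": asdict(result.correlation_affected),
        "correlation_fellow": asdict(result.correlation_fellow),
        "n_excluded": result.n_excluded,
        "thresholds": result.records.to_dict(orient="records"),
        "paths": paths,
    }
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info(
        "affected-eye correlation: r=%.3f p=%.4g n=%d",
        result.correlation_affected.r,
        result.correlation_affected.p,
        result.correlation_affected.n,
    )
    return summary
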