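"""Full study orchestration: DOF-combination enumeration, two-session
train/test evaluation per participant, and functional-control summaries.

For every participant and DOF combination the pipeline subsets both
sessions to that combination's movements (plus surrounding rest), selects
channels and trains the modified Kalman filter on the training session
only, predicts on the test session, and scores intended/unintended RMSE
per movement attempt.  Combination levels follow the study design: single
unidirectional movements (8), single bidirectional DOFs (4 opposing
pairs), a grasp with one wrist motion (8), a grasp with one wrist-pitch
and one wrist-roll motion (8), and both grasps with one wrist-pitch and
one wrist-roll motion (4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .decoder import apply_modifications, kf_predict, train_kf
from .metrics import FunctionalCriteria, aggregate, classify_functional
from .movements import DOF_AXES, MOVEMENT_CODES, REST, TrialProtocol, get_movement
from .preprocess import FeatureConfig, align_lag, expand_channels, subtract_baseline
from .selection import gram_schmidt_select
from .synth import SessionRecording, SynthConfig, generate_participant

__all__ = [
    "DofCombination",
    "ExperimentConfig",
    "ExperimentResult",
    "enumerate_combinations",
    "decode_targets",
    "subset_indices",
    "run_experiment",
    "summarize_functional",
    "default_cohort",
    "write_results",
]

LEVELS = ("1uni", "1bi", "2", "3", "4")

_GRASPS = ("HC", "TC")
_WRIST = ("WF", "WE", "WP", "WS")
_PITCH = ("WF", "WE")
_ROLL = ("WP", "WS")

_BI_PAIRS = (("HC", "HO"), ("TC", "TO"), ("WF", "WE"), ("WP", "WS"))


@dataclass(frozen=True)
class DofCombination:
    """Ordered movement subset defining the controllable DOFs."""

    movements: tuple[str, ...]
    mode: str  # "uni" | "bi"
    level: int

    def __post_init__(self) -> None:
        if self.mode not in ("uni", "bi"):
            raise ValueError(f"mode must be 'uni' or 'bi', got {self.mode!r}")
        for code in self.movements:
            get_movement(code)

    @property
    def name(self) -> str:
        return "/".join(self.movements)

    @property
    def n_dofs(self) -> int:
        return 1 if self.mode == "bi" else len(self.movements)


def enumerate_combinations(level: str) -> list[DofCombination]:
    """The study's DOF-combination scheme for one analysis level."""
    if level == "1uni":
        return [DofCombination((m,), "uni", 1) for m in MOVEMENT_CODES]
    if level == "1bi":
        return [DofCombination(pair, "bi", 1) for pair in _BI_PAIRS]
    if level == "2":
        return [DofCombination((g, w), "uni", 2) for g in _GRASPS for w in _WRIST]
    if level == "3":
        return [
            DofCombination((g, p, r), "uni", 3)
            for g in _GRASPS
            for p in _PITCH
            for r in _ROLL
        ]
    if level == "4":
        return [
            DofCombination(("HC", "TC", p, r), "uni", 4) for p in _PITCH for r in _ROLL
        ]
    raise ValueError(f"unknown level: {level!r} (expected one of {LEVELS})")


def decode_targets(
    kinematics: np.ndarray,
    labels: np.ndarray,
    combo: DofCombination,
    axis_names: list[str] | None = None,
) -> np.ndarray:
    """Per-combination decoding targets from the session's axis kinematics.

    uni: one column per movement, the movement's instructed magnitude in
    [0, 1] where its label is active; bi: one signed column for the shared
    axis in [-1, 1].  ``axis_names`` gives the kinematic column order
    (defaults to the canonical four DOF axes).
    """
    labels = np.asarray(labels, dtype=object)
    axes = list(axis_names) if axis_names is not None else list(DOF_AXES)
    t = len(labels)
    if combo.mode == "bi":
        axis = get_movement(combo.movements[0]).dof_axis
        col = np.zeros(t)
        for code in combo.movements:
            m = get_movement(code)
            if m.dof_axis != axis:
                raise ValueError("bi combination must share one DOF axis")
            mask = labels == code
            col[mask] = kinematics[mask, axes.index(axis)]
        return col[:, None]
    cols = []
    for code in combo.movements:
        m = get_movement(code)
        col = np.zeros(t)
        mask = labels == code
        col[mask] = np.abs(kinematics[mask, axes.index(m.dof_axis)])
        cols.append(col)
    return np.column_stack(cols)


def _label_runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    labels = np.asarray(labels, dtype=object)
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            start = i
    return runs


def subset_indices(labels: np.ndarray, combo: DofCombination) -> np.ndarray:
    """Chronological sample indices for the combination's movements plus the
    surrounding rest (the leading rest run and the rest run after each
    included attempt)."""
    runs = _label_runs(labels)
    keep: list[tuple[int, int]] = []
    wanted = set(combo.movements)
    for idx, (value, start, end) in enumerate(runs):
        if value in wanted:
            keep.append((start, end))
        elif value == REST and (
            idx == 0 or runs[idx - 1][0] in wanted
        ):
            keep.append((start, end))
    if not any(runs[i][0] in wanted for i in range(len(runs))):
        missing = wanted - {r[0] for r in runs}
        raise ValueError(f"session is missing movements: {sorted(missing)}")
    return np.concatenate([np.arange(s, e) for s, e in keep])


@dataclass
class ExperimentConfig:
    """Study-level configuration: cohort, levels, selection and decoder
    settings, functional criteria, and the master seed."""

    participants: list[SynthConfig]
    levels: tuple[str, ...] = LEVELS
    k: int = 48
    protocol: TrialProtocol = field(default_factory=TrialProtocol)
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    criteria: FunctionalCriteria = field(default_factory=FunctionalCriteria)
    threshold: float = 0.2
    clip: tuple[float, float] = (-1.0, 1.0)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.participants:
            raise ValueError("need at least one participant")
        if not self.levels:
            raise ValueError("need at least one level")
        for level in self.levels:
            if level not in LEVELS:
                raise ValueError(f"unknown level: {level!r}")


def default_cohort(
    n_participants: int = 7,
    master_seed: int = 0,
    **config_overrides,
) -> ExperimentConfig:
    """The default synthetic cohort: participants differ by sub-seed only."""
    children = np.random.SeedSequence(master_seed).spawn(n_participants)
    participants = [
        SynthConfig(seed=int(ss.generate_state(1)[0] % (2**31)), **config_overrides)
        for ss in children
    ]
    return ExperimentConfig(participants=participants, master_seed=master_seed)


@dataclass
class ExperimentResult:
    """Result bundle: per-attempt rows, per-combination summaries, best
    combination per participant and level, functional percentages, audit."""

    attempts: pd.DataFrame
    combos: pd.DataFrame
    best: pd.DataFrame
    summary: dict[str, int]
    audit: list[str]


@dataclass
class _ProcessedSession:
    features: np.ndarray  # expanded, baseline-subtracted (T x 528)
    kinematics: np.ndarray  # lag-aligned axis kinematics
    labels: np.ndarray  # lag-aligned labels
    lag_ms: float
    axis_names: list[str]


def _process_session(session: SessionRecording, fcfg: FeatureConfig) -> _ProcessedSession:
    expanded, _ = expand_channels(session.features, session.channel_names)
    expanded = subtract_baseline(expanded, session.labels)
    n_single = session.features.shape[1]
    aligned = align_lag(
        session.kinematics,
        expanded[:, :n_single],  # envelope from the single-ended channels
        replace(fcfg, out_rate_hz=session.rate_hz),
        labels=session.labels,
    )
    return _ProcessedSession(
        features=expanded,
        kinematics=aligned.kinematics,
        labels=aligned.labels,
        lag_ms=aligned.lag_ms,
        axis_names=list(session.axis_names),
    )


def _evaluate_combo(
    train: _ProcessedSession,
    test: _ProcessedSession,
    combo: DofCombination,
    config: ExperimentConfig,
    audit: list[str],
    who: str,
) -> metrics.RmseReport:
    idx_tr = subset_indices(train.labels, combo)
    idx_te = subset_indices(test.labels, combo)
    x_tr = train.features[idx_tr]
    y_tr = decode_targets(
        train.kinematics[idx_tr], train.labels[idx_tr], combo, train.axis_names
    )
    sel = gram_schmidt_select(x_tr, y_tr, k=config.k)
    model = train_kf(
        x_tr[:, sel.indices], y_tr, threshold=config.threshold, clip=config.clip
    )
    audit.append(
        f"{who} {combo.name}: selection+training on train session only "
        f"(T_train={len(idx_tr)}, k={len(sel.indices)})"
    )
    x_te = test.features[idx_te][:, sel.indices]
    labels_te = test.labels[idx_te]
    y_te = decode_targets(test.kinematics[idx_te], labels_te, combo, test.axis_names)
    modified = apply_modifications(kf_predict(model, x_te), model)

    rows = []
    if combo.mode == "bi":
        moving_col = {code: 0 for code in combo.movements}
    else:
        moving_col = {code: j for j, code in enumerate(combo.movements)}
    for code in combo.movements:
        for attempt, win in enumerate(metrics.attempt_windows(labels_te, code)):
            j = moving_col[code]
            others = [c for c in range(modified.shape[1]) if c != j]
            rows.append(
                {
                    "movement": code,
                    "attempt": attempt,
                    "intended": metrics.intended_rmse(
                        target=y_te[win, j], pred=modified[win, j]
                    ),
                    "unintended": (
                        metrics.unintended_rmse(pred_stationary=modified[win][:, others])
                        if others
                        else np.nan
                    ),
                }
            )
    return aggregate(pd.DataFrame(rows))


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full participant x combination sweep; deterministic under the
    master seed (participant sub-seeds live in their SynthConfigs)."""
    audit: list[str] = [f"master_seed={config.master_seed}"]
    attempt_rows: list[pd.DataFrame] = []
    combo_rows: list[dict] = []
    for p_idx, synth_cfg in enumerate(config.participants, start=1):
        who = f"P{p_idx}"
        train_raw, test_raw = generate_participant(synth_cfg, config.protocol)
        train = _process_session(train_raw, config.feature_config)
        test = _process_session(test_raw, config.feature_config)
        audit.append(
            f"{who}: lag train={train.lag_ms:.1f} ms, test={test.lag_ms:.1f} ms"
        )
        for level in config.levels:
            for combo in enumerate_combinations(level):
                report = _evaluate_combo(train, test, combo, config, audit, who)
                att = report.attempts.copy()
                att.insert(0, "participant", p_idx)
                att.insert(1, "level", level)
                att.insert(2, "combo", combo.name)
                attempt_rows.append(att)
                combo_rows.append(
                    {
                        "participant": p_idx,
                        "level": level,
                        "combo": combo.name,
                        "mode": combo.mode,
                        "intended": report.intended,
                        "unintended": (
                            np.nan if report.unintended is None else report.unintended
                        ),
                        "functional": classify_functional(
                            report.intended, report.unintended, config.criteria
                        ),
                    }
                )
    attempts = pd.concat(attempt_rows, ignore_index=True)
    combos = pd.DataFrame(combo_rows)

    best_rows = []
    for (p_idx, level), grp in combos.groupby(["participant", "level"], sort=False):
        summaries = {
            row.combo: (
                row.intended,
                None if pd.isna(row.unintended) else row.unintended,
            )
            for row in grp.itertuples()
        }
        name = metrics.select_best_combination(summaries)
        best_rows.append(grp[grp["combo"] == name].iloc[0].to_dict())
    best = pd.DataFrame(best_rows)
    summary = summarize_functional(best)
    return ExperimentResult(
        attempts=attempts, combos=combos, best=best, summary=summary, audit=audit
    )


def summarize_functional(best: pd.DataFrame, criteria: FunctionalCriteria | None = None) -> dict[str, int]:
    """Percentage of participants whose best combination is functional, per
    level, rounded to the nearest integer."""
    if len(best) == 0:
        raise ValueError("empty best-combination table")
    df = best
    if criteria is not None:
        flags = [
            classify_functional(
                row.intended,
                None if pd.isna(row.unintended) else row.unintended,
                criteria,
            )
            for row in df.itertuples()
        ]
        df = df.assign(functional=flags)
    out = {}
    for level, grp in df.groupby("level", sort=False):
        out[str(level)] = int(round(100.0 * grp["functional"].sum() / len(grp)))
    return out


def write_results(result: ExperimentResult, outdir, attempts_dir=None) -> None:
    """Write the result bundle as deterministic CSV/JSON artifacts.

    ``attempts_dir`` redirects the (large) per-attempt table elsewhere;
    by default it lands next to the summaries.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    for level, grp in result.combos.groupby("level", sort=False):
        grp.to_csv(outdir / f"level{level}_all.csv", index=False, float_format=fmt)
    for level, grp in result.best.groupby("level", sort=False):
        cols = ["participant", "combo", "intended", "unintended", "functional"]
        grp[cols].to_csv(outdir / f"level{level}_best.csv", index=False, float_format=fmt)
    attempts_dir = Path(attempts_dir) if attempts_dir is not None else outdir
    attempts_dir.mkdir(parents=True, exist_ok=True)
    result.attempts.to_csv(attempts_dir / "attempts.csv", index=False, float_format=fmt)
    with open(outdir / "summary.json", "w") as f:
        json.dump(result.summary, f, indent=2, sort_keys=True)
        f.write("\n")
    with open(outdir / "audit.log", "w") as f:
        f.write("\n".join(result.audit) + "\n")
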