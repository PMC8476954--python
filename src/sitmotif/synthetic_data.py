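"""Simulated smart-chair cohorts with known states, motifs and outcomes.

The generator emulates the study conditions of an office cohort observed
over working days: four-channel load-cell recordings at the chair corners,
a 1 Hz piecewise-stationary 2-D COP signal switching between sitting states
(stable sit, slight sway, big sway, off chair), a planted recurring motif —
an alternation of stable sitting and slight sway lasting between one and
three minutes — and per-day questionnaire scores whose morning-to-evening
low-back-pain (LBP) change is linked to the day's motif occurrence rate.

Cohort-level defaults mirror the observed study scale: 22 participants,
about four recorded days each, roughly 5.6 sitting hours per day, a motif
rate around 2 per 30 sitting minutes, and LBP-change day categories split
roughly 44/48/8 % between exacerbated / no change / improved.  A positive
``effect_size`` makes the planted rate highest on improved days and lowest
on exacerbated days.

All randomness flows through explicit seeds: identical specs give
byte-identical datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cop_io import COPSeries
from .exceptions import ConfigError
from .masa import Motif

logger = logging.getLogger(__name__)

STATE_LABELS = ("stable_sit", "slight_sway", "big_sway", "off_chair")

#: LBP-change categories in fixed order
CATEGORIES = ("exacerbated", "no_change", "improved")

#: day-category probabilities matching the observed 40/43/7 split over 90 days
CATEGORY_PROBS = (40 / 90, 43 / 90, 7 / 90)

#: planted-rate offsets per category, scaled by ``effect_size``; the observed
#: asymmetry (improvement stands out more than exacerbation) is kept
CATEGORY_RATE_DELTA = {"exacerbated": -0.25, "no_change": 0.0, "improved": 1.0}

#: symptom scores are mostly a participant trait (baseline mean, sd between
#: participants) with a smaller day-level shift by LBP-change category and
#: day-to-day noise; the category-conditional marginals then emerge largely
#: through participant composition, as in the observed cohort
SYMPTOM_BASELINES = {"sleepiness": (6.6, 1.6), "fullness": (4.3, 3.0)}
SYMPTOM_DAY_SHIFT = {
    "sleepiness": {"exacerbated": -0.2, "no_change": 0.2, "improved": -0.1},
    "fullness": {"exacerbated": -0.4, "no_change": 0.4, "improved": -0.7},
}
SYMPTOM_DAY_SD = 1.2

TIME_SLOTS = ("0900", "1130", "1400", "1700")

#: background switching kernel by state label.  Office sitting alternates
#: between stable posture and slight sway more often than through any other
#: state pair — the stable/slight alternation is the dominant recurring
#: pattern even before planting — while big sways are occasional excursions
#: and chair-leaving episodes punctuate the day.  Together with the default
#: dwell times this yields roughly 70 % chair presence (about 5.6 h of an
#: 8 h day) and a background alternation rate around 0.6 per 30 sitting
#: minutes, so planted occurrences dominate day-to-day rate variation.
DEFAULT_TRANSITIONS = {
    "stable_sit": {"stable_sit": 0.0, "slight_sway": 0.42, "big_sway": 0.13,
                   "off_chair": 0.45},
    "slight_sway": {"stable_sit": 0.45, "slight_sway": 0.0, "big_sway": 0.20,
                    "off_chair": 0.35},
    "big_sway": {"stable_sit": 0.45, "slight_sway": 0.35, "big_sway": 0.0,
                 "off_chair": 0.20},
    "off_chair": {"stable_sit": 0.60, "slight_sway": 0.28, "big_sway": 0.12,
                  "off_chair": 0.0},
}


def uniform_transitions(k: int) -> np.ndarray:
    """Uniform switching among the other states (balanced occupancy);
    the conventional background for segmentation benchmarks."""
    if k < 2:
        raise ConfigError("need at least two states")
    P = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(P, 0.0)
    return P


def label_transition_matrix(specs) -> np.ndarray:
    """Row-stochastic switching matrix for a spec list from the label kernel.

    Probability mass on labels absent from ``specs`` is dropped and rows are
    renormalised; several specs sharing a label split its mass evenly.
    Self-transitions are excluded (they would merge runs).
    """
    labels = [s.label for s in specs]
    k = len(specs)
    P = np.zeros((k, k))
    for i, src in enumerate(labels):
        row = DEFAULT_TRANSITIONS[src]
        for j, dst in enumerate(labels):
            if i == j:
                continue
            share = sum(1 for l in labels if l == dst)
            P[i, j] = row[dst] / share
        if P[i].sum() == 0:  # e.g. a single-label spec list
            P[i, [j for j in range(k) if j != i]] = 1.0
        P[i] /= P[i].sum()
    return P


def _cov_from(sd_x: float, sd_y: float, corr: float) -> np.ndarray:
    c = corr * sd_x * sd_y
    return np.array([[sd_x ** 2, c], [c, sd_y ** 2]])


@dataclass(frozen=True)
class StateSpec:
    """Within-state COP distribution: a 2x2 precision (partial-correlation
    structure), an optional per-second mean drift, and a semantic label.

    ``off_chair`` states emit absent samples (near-zero total load)."""

    state_id: int
    precision: np.ndarray
    mean_drift: np.ndarray = field(default_factory=lambda: np.zeros(2))
    label: str = "stable_sit"
    dwell: float = 60.0  # mean run length, seconds

    def __post_init__(self) -> None:
        prec = np.asarray(self.precision, dtype=float)
        object.__setattr__(self, "precision", prec)
        object.__setattr__(self, "mean_drift", np.asarray(self.mean_drift, dtype=float))
        if prec.shape[0] != prec.shape[1] or not np.allclose(prec, prec.T):
            raise ConfigError("precision must be symmetric")
        if np.linalg.eigvalsh(prec).min() <= 0:
            raise ConfigError("precision must be positive definite")
        if self.label not in STATE_LABELS:
            raise ConfigError(f"label must be one of {STATE_LABELS}")

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


def default_state_specs() -> list[StateSpec]:
    """The four canonical sitting states at realistic COP scales (kg units).

    Stable sitting is tight and weakly coupled; slight sway is moderate with
    positively coupled axes; big sway is large with negatively coupled axes;
    off-chair produces absent samples.  Dwell times put roughly three
    quarters of the day on the chair.
    """
    return [
        StateSpec(1, np.linalg.inv(_cov_from(0.08, 0.08, 0.2)), label="stable_sit", dwell=320.0),
        StateSpec(2, np.linalg.inv(_cov_from(0.40, 0.40, 0.6)), label="slight_sway", dwell=110.0),
        StateSpec(3, np.linalg.inv(_cov_from(1.50, 1.50, -0.5)), label="big_sway", dwell=45.0),
        StateSpec(4, np.linalg.inv(_cov_from(0.10, 0.10, 0.0)), label="off_chair", dwell=190.0),
    ]


def demo_state_specs(k: int = 4, dwell: float = 60.0) -> list[StateSpec]:
    """``k`` well-separated seated states (no off-chair) for segmentation
    experiments: distinct scales, anisotropies and partial-correlation signs.

    The fourth state is a directional rock — movement almost entirely along
    the left-right axis — standing in for lean-type behaviour."""
    params = [(0.08, 0.08, 0.2), (0.40, 0.40, 0.6), (1.50, 1.50, -0.5), (1.20, 0.15, 0.0)]
    if not 1 <= k <= len(params):
        raise ConfigError(f"k must be in 1..{len(params)}")
    labels = ("stable_sit", "slight_sway", "big_sway", "big_sway")
    return [StateSpec(i + 1, np.linalg.inv(_cov_from(*params[i])), label=labels[i], dwell=dwell)
            for i in range(k)]


@dataclass
class CohortSpec:
    """Study-scale cohort defaults; see the module docstring."""

    n_participants: int = 22
    days_per_participant: int = 4
    motif: Motif = field(default_factory=lambda: Motif((1, 2, 1)))
    base_rate: float = 2.4
    effect_size: float = 2.7
    noise_sd: float = 0.05
    seed: int = 0
    day_hours: float = 8.0
    hz: int = 1
    state_specs: list = field(default_factory=default_state_specs)
    category_probs: tuple = CATEGORY_PROBS

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0 (higher motif rate in "
                              "the improved category)")


@dataclass
class CohortData:
    """``loadcells`` maps (participant_id, date) -> load-cell frame; the
    questionnaire, ground-truth and metadata tables are DataFrames."""

    loadcells: dict
    questionnaire: pd.DataFrame
    ground_truth: pd.DataFrame
    metadata: pd.DataFrame


# ---------------------------------------------------------------------------
# state path simulation


def _spec_index(specs: list[StateSpec]) -> dict:
    idx = {}
    for i, spec in enumerate(specs):
        if spec.state_id in idx:
            raise ConfigError(f"duplicate state id {spec.state_id}")
        idx[spec.state_id] = i
    return idx


def _draw_instance_lengths(motif: Motif, rng) -> np.ndarray:
    """Per-state run lengths: 1-60 s each, total under three minutes."""
    while True:
        lengths = rng.integers(1, 61, size=len(motif))
        if lengths.sum() < 180:
            return lengths


def simulate_state_sequence(
    specs: list[StateSpec],
    T: int,
    dwell=None,
    planted_motif: Motif | None = None,
    motif_rate: float = 0.0,
    seed: int = 0,
    transitions: np.ndarray | None = None,
) -> tuple[np.ndarray, list]:
    """Semi-Markov state path with planted motif instances.

    Background runs have geometric lengths (mean ``dwell``, per-state when
    ``dwell`` is None, using each spec's own dwell); switching follows
    ``transitions`` (row-stochastic, zero diagonal), by default the
    label-based office-sitting kernel.  Motif instances — consecutive runs
    following
    the motif's state order, each state 1-60 s, instance < 3 min — are
    planted at ``motif_rate`` per 30 min of on-chair time, overwriting the
    background at uniformly drawn non-overlapping positions.

    Returns the state-id sequence (length T) and the planted instance list
    of half-open ``(start, end)`` index pairs.
    """
    if T <= 0:
        raise ConfigError("T must be > 0")
    idx = _spec_index(specs)
    if planted_motif is not None:
        unknown = [s for s in planted_motif.states if s not in idx]
        if unknown:
            raise ConfigError(f"motif references unknown state id(s) {unknown}")
    rng = np.random.default_rng(seed)
    dwells = np.array([spec.dwell for spec in specs]) if dwell is None else \
        np.full(len(specs), float(dwell))
    if np.any(dwells <= 0):
        raise ConfigError("dwell must be > 0")

    if transitions is None and len(specs) > 1:
        transitions = label_transition_matrix(specs)
    if transitions is not None:
        P = np.asarray(transitions, dtype=float)
        if P.shape != (len(specs), len(specs)) or np.any(np.diag(P) != 0) or \
                not np.allclose(P.sum(axis=1), 1.0):
            raise ConfigError("transitions must be row-stochastic with zero diagonal")

    ids = np.array([spec.state_id for spec in specs])
    seq = np.empty(T, dtype=np.int64)
    pos = 0
    cur = int(rng.integers(len(specs)))
    while pos < T:
        run = int(rng.geometric(1.0 / dwells[cur]))  # geometric, mean = dwell
        seq[pos:pos + run] = ids[cur]
        pos += run
        if len(specs) > 1:
            cur = int(rng.choice(len(specs), p=P[cur]))

    instances: list = []
    if planted_motif is not None and motif_rate > 0:
        off_ids = {spec.state_id for spec in specs if spec.label == "off_chair"}
        seated = ~np.isin(seq, list(off_ids)) if off_ids else np.ones(T, dtype=bool)
        t_seated = int(seated.sum())
        n_plant = int(rng.poisson(motif_rate * t_seated / 1800.0))
        occupied = np.zeros(T, dtype=bool)
        attempts = 0
        while len(instances) < n_plant and attempts < 50 * max(n_plant, 1):
            attempts += 1
            lengths = _draw_instance_lengths(planted_motif, rng)
            total = int(lengths.sum())
            start = int(rng.integers(0, max(T - total, 1)))
            span = slice(start, start + total)
            if start + total > T or occupied[span].any() or not seated[span].all():
                continue
            pos = start
            for s, l in zip(planted_motif.states, lengths):
                seq[pos:pos + l] = s
                pos += l
            occupied[span] = True
            instances.append((start, start + total))
        instances.sort()
        if len(instances) < n_plant:
            logger.info("simulate_state_sequence: planted %d of %d requested instances",
                        len(instances), n_plant)
    return seq, instances


def emit_cop(state_seq: np.ndarray, specs: list[StateSpec], seed: int = 0) -> COPSeries:
    """Draw 1 Hz COP samples for a state path.

    Each present sample is Gaussian with its state's precision, centred on
    the state's drift line (``mean_drift`` per second within the run);
    off-chair states emit absent samples.
    """
    idx = _spec_index(specs)
    seq = np.asarray(state_seq, dtype=np.int64)
    unknown = set(np.unique(seq)) - set(idx)
    if unknown:
        raise ConfigError(f"state sequence references unknown ids {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    T = len(seq)
    x = np.full(T, np.nan)
    y = np.full(T, np.nan)
    present = np.ones(T, dtype=bool)
    change = np.flatnonzero(np.diff(seq)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [T])))
    run_elapsed = np.arange(T) - np.repeat(starts, lengths)
    for sid, i in idx.items():
        spec = specs[i]
        mask = seq == sid
        m = int(mask.sum())
        if m == 0:
            continue
        if spec.label == "off_chair":
            present[mask] = False
            continue
        cov = spec.covariance
        chol = np.linalg.cholesky(cov)
        draws = rng.standard_normal((m, 2)) @ chol.T
        drift = np.outer(run_elapsed[mask], spec.mean_drift)
        x[mask] = draws[:, 0] + drift[:, 0]
        y[mask] = draws[:, 1] + drift[:, 1]
    samples = pd.DataFrame({"t": np.arange(T, dtype=float), "x": x, "y": y,
                            "present": present})
    return COPSeries(samples=samples)


def emit_loadcells(
    cop: COPSeries,
    body_weight: float,
    hz: int = 1,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Invert the COP map to four corner loads A1..A4 at ``hz`` samples/s.

    The symmetric inverse ``A = W/4 + corner .(x, y)`` reproduces the input
    COP exactly after downsampling when noise-free.  COP values outside the
    representable corner hull (|x| + |y| > W/4) are clipped; the clip count
    is returned.  Absent samples emit zero load.  Additive Gaussian sensor
    noise of ``noise_sd`` kg is applied per channel and sample, clipped at 0.
    """
    if body_weight <= 0:
        raise ConfigError("body_weight must be > 0")
    if hz < 1:
        raise ConfigError("hz must be >= 1")
    rng = np.random.default_rng(seed)
    xy = cop.xy
    present = cop.present
    W = float(body_weight)
    limit = W / 4.0
    x = np.where(present, xy[:, 0], 0.0)
    y = np.where(present, xy[:, 1], 0.0)
    scale = np.abs(x) + np.abs(y)
    over = present & (scale > limit)
    n_clipped = int(np.count_nonzero(over))
    if n_clipped:
        shrink = limit / scale[over]
        x[over] *= shrink
        y[over] *= shrink
        logger.warning("emit_loadcells: %d COP samples outside the corner hull clipped",
                       n_clipped)
    # corner solution: A1 FL, A2 BL, A3 FR, A4 BR
    a = np.stack([W / 4.0 - x + y, W / 4.0 - x - y, W / 4.0 + x + y, W / 4.0 + x - y],
                 axis=1)
    a[~present] = 0.0
    T = len(xy)
    a_hr = np.repeat(a, hz, axis=0)
    t_hr = np.repeat(cop.samples["t"].to_numpy(), hz) + np.tile(np.arange(hz) / hz, T)
    if noise_sd > 0:
        a_hr = np.clip(a_hr + rng.normal(0.0, noise_sd, size=a_hr.shape), 0.0, None)
    frame = pd.DataFrame({"t": t_hr, "a1_kg": a_hr[:, 0], "a2_kg": a_hr[:, 1],
                          "a3_kg": a_hr[:, 2], "a4_kg": a_hr[:, 3]})
    return frame, n_clipped


# ---------------------------------------------------------------------------
# cohort simulation


def _questionnaire_scores(category: str, baselines: dict, rng) -> dict:
    """Slot-wise LBP plus symptom scores consistent with the day's
    LBP-change category (change = morning minus evening score).

    ``baselines`` carries the participant's trait levels for sleepiness and
    fullness; the day category adds only a small shift on top."""
    if category == "improved":
        morning = int(rng.integers(2, 9))
        evening = morning - int(rng.integers(1, min(4, morning + 1)))
    elif category == "exacerbated":
        morning = int(rng.integers(0, 8))
        evening = morning + int(rng.integers(1, 4))
    else:
        morning = int(rng.integers(0, 11))
        evening = morning
    evening = int(np.clip(evening, 0, 10))
    mid = np.clip(np.round(np.linspace(morning, evening, 4)[1:3]
                           + rng.normal(0, 1, 2)), 0, 10).astype(int)
    lbp = [morning, int(mid[0]), int(mid[1]), evening]
    out = {"lbp": lbp}
    for symptom, shifts in SYMPTOM_DAY_SHIFT.items():
        centre = baselines[symptom] + shifts[category]
        vals = np.clip(np.round(rng.normal(centre, SYMPTOM_DAY_SD, size=4)),
                       0, 10).astype(int)
        out[symptom] = vals.tolist()
    return out


def planted_rate(spec: CohortSpec, category: str) -> float:
    """Planted motif rate (/30 sitting min) for a day of the given category."""
    return max(0.0, spec.base_rate + spec.effect_size * CATEGORY_RATE_DELTA[category])


def simulate_cohort(spec: CohortSpec) -> CohortData:
    """Generate a full cohort: recordings, questionnaires and ground truth."""
    rng = np.random.default_rng(spec.seed)
    loadcells = {}
    q_rows, gt_rows, meta_rows = [], [], []
    T = int(spec.day_hours * 3600)
    start_date = pd.Timestamp("2017-10-02")
    for p in range(spec.n_participants):
        pid = f"P{p + 1:02d}"
        sex = int(rng.integers(0, 2))
        weight = float(np.clip(rng.normal(65.1, 10.0), 40.0, 100.0))
        baselines = {s: float(rng.normal(m, sd))
                     for s, (m, sd) in SYMPTOM_BASELINES.items()}
        meta_rows.append({"participant_id": pid, "sex": sex, "weight_kg": weight})
        for d in range(spec.days_per_participant):
            date = (start_date + pd.Timedelta(days=7 * d + p % 5)).date().isoformat()
            category = CATEGORIES[int(rng.choice(len(CATEGORIES), p=spec.category_probs))]
            rate = planted_rate(spec, category)
            day_seed = int(rng.integers(2 ** 31))
            seq, instances = simulate_state_sequence(
                spec.state_specs, T, planted_motif=spec.motif,
                motif_rate=rate, seed=day_seed)
            cop = emit_cop(seq, spec.state_specs, seed=day_seed + 1)
            frame, _ = emit_loadcells(cop, weight, hz=spec.hz, seed=day_seed + 2,
                                      noise_sd=spec.noise_sd)
            # anchor timestamps at 09:00 local on the recording date
            frame["t"] = frame["t"] + pd.Timestamp(f"{date} 09:00:00").timestamp()
            loadcells[(pid, date)] = frame
            scores = _questionnaire_scores(category, baselines, rng)
            for slot_i, slot in enumerate(TIME_SLOTS):
                q_rows.append({
                    "participant_id": pid, "date": date, "time_slot": slot,
                    "lbp": scores["lbp"][slot_i],
                    "sleepiness": scores["sleepiness"][slot_i],
                    "fullness": scores["fullness"][slot_i],
                })
            sitting_s = int(cop.present.sum())
            gt_rows.append({
                "participant_id": pid, "date": date, "category": category,
                "planted_rate_30min": rate,
                "n_planted_instances": len(instances),
                "true_rate_30min": len(instances) / (sitting_s / 1800.0)
                if sitting_s else np.nan,
                "sitting_hours": sitting_s / 3600.0,
                "sex": sex, "weight_kg": weight,
            })
    return CohortData(
        loadcells=loadcells,
        questionnaire=pd.DataFrame(q_rows),
        ground_truth=pd.DataFrame(gt_rows),
        metadata=pd.DataFrame(meta_rows),
    )


def write_cohort(cohort: CohortData, outdir) -> None:
    """Write load-cell, questionnaire and ground-truth CSVs to ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for (pid, date), frame in cohort.loadcells.items():
        f = frame.copy()
        f["timestamp"] = pd.to_datetime(f.pop("t"), unit="s").dt.strftime(
            "%Y-%m-%dT%H:%M:%S.%f")
        f[["timestamp", "a1_kg", "a2_kg", "a3_kg", "a4_kg"]].to_csv(
            out / f"loadcell_{pid}_{date}.csv", index=False)
    cohort.questionnaire.to_csv(out / "questionnaire.csv", index=False)
    cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    cohort.metadata.to_csv(out / "metadata.csv", index=False)
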