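"""The 16-member family of per-time-step logistic exit-choice models.

Each model is a logistic regression on the features of one decision sample.
Four information components are switched on or off across the family — queue
length (Q), queue flow (F), exit width (W) and shortest-route visibility
(S) — giving one model per subset of {Q, F, W, S}.  Three components are
always included: a constant bias, a proximity term gated by a distance
threshold, and a blocked-in-queue (jam) term.

The log-odds of preferring the top exit are

    eta = p1
        + [S] p2 * s_vis
        + [W] p3 * w_adv
        + [Q] p4 * q_adv
        + [F] p6 * f_adv
        +     p8 * d_adv * 1[|d_adv| >= p9]
        +     p10 * jam

and P(choice = top) = 1 / (1 + exp(-eta)).  Coefficients of excluded
components are absent from a model's parameter space (not fixed-at-zero free
parameters), so marginal-likelihood comparisons penalise model dimension.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .envsim import BOTTOM, TOP, SimHistory
from .features import (
    DEFAULT_FLOW_WINDOW,
    DEFAULT_SAMPLE_INTERVAL,
    ParticipantTrajectory,
    _static_features,
    detect_jam,
)

__all__ = [
    "ModelSpec",
    "ParameterVector",
    "SpecificationError",
    "enumerate_model_family",
    "linear_predictor",
    "choice_probability",
    "log_likelihood",
    "simulate_participant",
]

COMPONENTS = ("Q", "F", "W", "S")
#: coefficient carried by each optional component
COMPONENT_COEF = {"S": "p2", "W": "p3", "Q": "p4", "F": "p6"}
#: coefficients present in every model
ALWAYS_COEFS = ("p1", "p8", "p9", "p10")


class SpecificationError(ValueError):
    """Parameter vector does not match the model specification."""


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model family: which components are switched on."""

    include_Q: bool
    include_F: bool
    include_W: bool
    include_S: bool

    @property
    def tag(self) -> str:
        """Four-character tag, excluded components shown as '-': 'QFWS', 'QF-S'."""
        return "".join(
            c if getattr(self, f"include_{c}") else "-" for c in COMPONENTS
        )

    @property
    def size(self) -> int:
        return sum(
            getattr(self, f"include_{c}") for c in COMPONENTS
        )

    @property
    def block(self) -> str:
        """Q/F-inclusion block used in the ranking layout: QF, Q, F or none."""
        if self.include_Q and self.include_F:
            return "QF"
        if self.include_Q:
            return "Q"
        if self.include_F:
            return "F"
        return "none"

    def required_coefficients(self) -> tuple[str, ...]:
        extra = tuple(
            COMPONENT_COEF[c] for c in COMPONENTS if getattr(self, f"include_{c}")
        )
        return ALWAYS_COEFS + extra

    @classmethod
    def from_components(cls, comps) -> "ModelSpec":
        comps = set(comps)
        unknown = comps - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")
        return cls(*(c in comps for c in COMPONENTS))

    @classmethod
    def from_tag(cls, tag: str) -> "ModelSpec":
        if len(tag) != 4:
            raise ValueError(f"tag must have four characters, got {tag!r}")
        return cls.from_components(c for c in tag if c != "-")


def enumerate_model_family() -> list[ModelSpec]:
    """All 16 subsets of {Q, F, W, S}, deterministically ordered.

    The full model comes first, then specs by decreasing subset size,
    lexicographic by tag within each size.
    """
    specs = []
    for size in range(4, -1, -1):
        group = [
            ModelSpec.from_components(comb)
            for comb in combinations(COMPONENTS, size)
        ]
        specs.extend(sorted(group, key=lambda s: s.tag))
    return specs


@dataclass(frozen=True)
class ParameterVector:
    """Named coefficients for one model.

    Units: p1, p2, p10 dimensionless; p3 per metre; p4 per person; p6 per
    (person/second); p8 per metre; p9 metres (distance-difference threshold,
    non-negative).
    """

    p1: float = 0.0
    p2: float | None = None
    p3: float | None = None
    p4: float | None = None
    p6: float | None = None
    p8: float = 0.0
    p9: float = 0.0
    p10: float = 0.0

    def __post_init__(self) -> None:
        if self.p9 < 0:
            raise SpecificationError("p9 (distance threshold) must be >= 0")

    def for_spec(self, spec: ModelSpec) -> dict:
        """Coefficient dict for ``spec``; raises if a required one is missing."""
        out = {}
        for name in spec.required_coefficients():
            value = getattr(self, name)
            if value is None:
                raise SpecificationError(
                    f"model {spec.tag} requires coefficient {name}"
                )
            out[name] = float(value)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterVector":
        return cls(**{k: v for k, v in d.items()})


_FEATURE_FOR_COEF = {"p2": "s_vis", "p3": "w_adv", "p4": "q_adv", "p6": "f_adv"}


def _eta_arrays(rows: pd.DataFrame, coefs: dict) -> np.ndarray:
    """Vectorised linear predictor over a feature frame."""
    eta = np.full(len(rows), coefs["p1"], dtype=float)
    for coef, col in _FEATURE_FOR_COEF.items():
        if coef in coefs:
            eta += coefs[coef] * rows[col].to_numpy(dtype=float)
    d_adv = rows["d_adv"].to_numpy(dtype=float)
    gate = np.abs(d_adv) >= coefs["p9"]
    eta += coefs["p8"] * d_adv * gate
    eta += coefs["p10"] * rows["jam"].to_numpy(dtype=float)
    return eta


def linear_predictor(row, params: ParameterVector, spec: ModelSpec) -> float:
    """Log-odds of preferring the top exit for one feature row.

    ``row`` may be a mapping, a namedtuple-style row or a pandas Series with
    fields q_adv, f_adv, w_adv, s_vis, d_adv, jam.
    """
    coefs = params.for_spec(spec)
    get = row.__getitem__ if hasattr(row, "__getitem__") else lambda k: getattr(row, k)
    eta = coefs["p1"]
    for coef, col in _FEATURE_FOR_COEF.items():
        if coef in coefs:
            eta += coefs[coef] * float(get(col))
    d_adv = float(get("d_adv"))
    if abs(d_adv) >= coefs["p9"]:
        eta += coefs["p8"] * d_adv
    eta += coefs["p10"] * float(get("jam"))
    return eta


def _logistic(eta):
    return 0.5 * (1.0 + np.tanh(0.5 * eta))  # numerically stable sigmoid


def choice_probability(row, params: ParameterVector, spec: ModelSpec) -> float:
    """P(choice = top) for one feature row; P(top) + P(bottom) = 1."""
    return float(_logistic(linear_predictor(row, params, spec)))


def log_likelihood(dataset: pd.DataFrame, params: ParameterVector, spec: ModelSpec) -> float:
    """Sum of log P(observed choice) over all rows of a decision dataset.

    Rows are treated as conditionally independent given their features.
    ``dataset`` is a feature frame with a ``choice`` column in
    {"top", "bottom"}.
    """
    if len(dataset) == 0:
        raise ValueError("decision dataset is empty")
    coefs = params.for_spec(spec)
    eta = _eta_arrays(dataset, coefs)
    y = (dataset["choice"].to_numpy() == TOP).astype(float)
    # log sigmoid(eta) for y=1, log sigmoid(-eta) for y=0, stably:
    z = np.where(y == 1.0, eta, -eta)
    return float(np.sum(-np.logaddexp(0.0, -z)))


def make_loglik(dataset: pd.DataFrame, spec: ModelSpec):
    """Closure mapping a coefficient dict to the dataset log-likelihood.

    Used by the evidence estimator; precomputes feature arrays once.
    """
    if len(dataset) == 0:
        raise ValueError("decision dataset is empty")
    names = spec.required_coefficients()
    cols = {
        coef: dataset[col].to_numpy(dtype=float)
        for coef, col in _FEATURE_FOR_COEF.items()
        if coef in names
    }
    d_adv = dataset["d_adv"].to_numpy(dtype=float)
    abs_d = np.abs(d_adv)
    jam = dataset["jam"].to_numpy(dtype=float)
    y_top = dataset["choice"].to_numpy() == TOP

    def loglik(theta: dict) -> float:
        eta = theta["p1"] + theta["p8"] * d_adv * (abs_d >= theta["p9"]) + theta["p10"] * jam
        for coef, col in cols.items():
            eta = eta + theta[coef] * col
        z = np.where(y_top, eta, -eta)
        return float(np.sum(-np.logaddexp(0.0, -z)))

    return loglik


# ---------------------------------------------------------------------------
# generative participant
# ---------------------------------------------------------------------------

PARTICIPANT_SPEED = 1.3  # m/s
EXIT_PASS_MARGIN = 0.6  # metres beyond the wall at which the run ends
#: lateral offset of the participant's waiting spot from the queue axis,
#: metres, away from the room midline -- the participant hovers at the back
#: of the queue rather than standing in line, so queued pedestrians can
#: block its straight path to the opposite exit
QUEUE_HOVER_OFFSET = 0.5


def simulate_participant(
    history: SimHistory,
    spec: ModelSpec,
    params: ParameterVector,
    interval: float = DEFAULT_SAMPLE_INTERVAL,
    seed: int = 0,
    participant_id: str = "sim",
    condition: str = "control",
    age: float = 23.0,
    gender: int = 0,
    start: tuple[float, float] = (-3.0, 0.0),
    flow_window: float = DEFAULT_FLOW_WINDOW,
    time_cap: float = 120.0,
) -> ParticipantTrajectory:
    """Generative twin of the fitted model: a participant whose per-tick
    preference is drawn from the choice model while it walks through the
    simulated evacuation.

    At every tick the participant's feature row is computed against
    ``history``, a preference is drawn from the model's choice probability,
    and the participant walks towards the preferred exit for one interval.
    Inside the queue zone it falls in behind the scripted queue (holding a
    spot just behind the current tail) and passes through the exit once that
    queue has drained.  The trajectory ends just beyond the exit wall; a
    participant still inside at ``time_cap`` is returned flagged incomplete.
    """
    from .envsim import QUEUE_SLOT_SPACING, queue_flow as _qf
    from .envsim import FlowUnavailable

    rng = np.random.default_rng(seed)
    env = history.env
    pos = np.array(start, dtype=float)
    w_adv, s_vis = _static_features(env)
    coefs = params.for_spec(spec)

    times, positions, preferred = [], [], []
    t = 0.0
    complete = False
    while t <= time_cap:
        q_top = history.queue_length_at(t, TOP)
        q_bot = history.queue_length_at(t, BOTTOM)
        try:
            f_adv = _qf(history, TOP, t, flow_window) - _qf(history, BOTTOM, t, flow_window)
        except FlowUnavailable:
            f_adv = 0.0
        d_top = float(np.linalg.norm(pos - env.exit_centre(TOP)))
        d_bot = float(np.linalg.norm(pos - env.exit_centre(BOTTOM)))
        row = {
            "q_adv": q_bot - q_top,
            "f_adv": f_adv,
            "w_adv": w_adv,
            "s_vis": s_vis,
            "d_adv": d_bot - d_top,
            "jam": 0,
        }
        # provisional queue membership from the previous tick's preference
        prev_choice = preferred[-1] if preferred else None
        if prev_choice is not None:
            in_queue = (
                prev_choice
                if np.linalg.norm(pos - env.exit_centre(prev_choice))
                <= history.params.capture_radius
                else None
            )
            if in_queue is not None:
                row["jam"] = detect_jam(history.state_at(t), pos, in_queue)
        eta = linear_predictor(row, params, spec)
        choice = TOP if rng.random() < _logistic(eta) else BOTTOM
        times.append(t)
        positions.append(pos.copy())
        preferred.append(choice)

        # walk one interval towards the preferred exit
        centre = env.exit_centre(choice)
        q_now = history.queue_length_at(t, choice)
        if q_now > 0:
            # hover one slot behind the scripted queue tail, offset to the
            # outside of the queue line
            lateral = QUEUE_HOVER_OFFSET if choice == TOP else -QUEUE_HOVER_OFFSET
            target = centre + np.array([-(QUEUE_SLOT_SPACING * (q_now + 1)), lateral])
        else:
            target = centre + np.array([EXIT_PASS_MARGIN, 0.0])
        delta = target - pos
        dist = float(np.hypot(*delta))
        step_len = PARTICIPANT_SPEED * interval
        if dist <= step_len:
            pos = target.copy()
        else:
            pos = pos + delta * (step_len / dist)
        t += interval
        if pos[0] >= env.wall_x:
            times.append(t)
            positions.append(pos.copy())
            preferred.append(choice)
            complete = True
            break

    return ParticipantTrajectory(
        participant_id=participant_id,
        condition=condition,
        age=age,
        gender=gender,
        times=np.asarray(times),
        positions=np.asarray(positions),
        preferred=np.asarray(preferred),
        complete=complete,
    )
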