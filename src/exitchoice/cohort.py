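"""Synthetic cohorts with known generating truth.

A cohort emulates the study design end to end: 8 experimental conditions
(all combinations of treatments S, W and M), 58 participants per condition
by default, each participant experiencing a freshly simulated evacuation of
a scripted crowd that splits evenly between the exits (the wider exit's
queue draining faster under treatment W), with the participant's per-tick
exit preference drawn from a known member of the choice-model family.  Ages
are drawn from a shifted log-normal concentrated near 23 years with about
5% of draws above 35; gender is balanced Bernoulli coded {0, 1}.

The generating truth (model spec, coefficients, seeds) is stored alongside
the outputs but kept out of every analysis input, so downstream stages are
blind to it; recovery tests read it from the truth report only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import envsim
from .envsim import CrowdParams, EnvironmentConfig, build_environment, run_evacuation
from .features import (
    DEFAULT_SAMPLE_INTERVAL,
    ParticipantTrajectory,
    behavioural_summary,
    sample_decision_points,
)
from .choicemodels import ModelSpec, ParameterVector, simulate_participant

__all__ = [
    "CohortDesign",
    "Cohort",
    "generate_cohort",
    "truth_report",
    "CONDITIONS",
    "condition_flags",
    "condition_name",
]

# the 8-cell factorial design over treatments (S, W, M)
CONDITIONS = (
    "control",
    "S",
    "W",
    "M",
    "SW",
    "SM",
    "WM",
    "SWM",
)

#: age model: age = AGE_SHIFT + LogNormal(mu, sigma); median 23 with ~5%
#: of participants above 35
AGE_SHIFT = 16.0
AGE_MU = float(np.log(23.0 - AGE_SHIFT))
AGE_SIGMA = float((np.log(35.0 - AGE_SHIFT) - AGE_MU) / 1.6448536269514722)


def condition_flags(name: str) -> dict:
    if name not in CONDITIONS:
        raise ValueError(f"unknown condition {name!r}")
    return {
        "treatment_S": "S" in name,
        "treatment_W": "W" in name,
        "treatment_M": "M" in name,
    }


def condition_name(S: bool, W: bool, M: bool) -> str:
    name = ("S" if S else "") + ("W" if W else "") + ("M" if M else "")
    return name or "control"


#: default generating model: time-dependent information only (Q and F),
#: with the always-on proximity and jam components active
DEFAULT_GENERATING_SPEC = ModelSpec(include_Q=True, include_F=True, include_W=False, include_S=False)
DEFAULT_PARAMS_NON_M = ParameterVector(p1=0.0, p4=0.4, p6=1.0, p8=2.0, p9=0.0, p10=5.0)
#: under treatment M decisions are stickier: the proximity and jam effects
#: are doubled, reproducing the observed drop in P(change)
DEFAULT_PARAMS_M = ParameterVector(p1=0.0, p4=0.4, p6=1.0, p8=4.0, p9=0.0, p10=10.0)


@dataclass
class CohortDesign:
    """Everything needed to regenerate a cohort deterministically."""

    n_per_condition: int = 58
    conditions: tuple = CONDITIONS
    seed: int = 0
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL
    gender_balance: float = 0.5
    spec_non_m: ModelSpec = DEFAULT_GENERATING_SPEC
    params_non_m: ParameterVector = DEFAULT_PARAMS_NON_M
    spec_m: ModelSpec = DEFAULT_GENERATING_SPEC
    params_m: ParameterVector = DEFAULT_PARAMS_M
    crowd: CrowdParams = field(default_factory=CrowdParams)
    env_base: EnvironmentConfig = field(default_factory=EnvironmentConfig)

    def __post_init__(self) -> None:
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be unique")

    @property
    def n_total(self) -> int:
        return self.n_per_condition * len(self.conditions)

    def to_dict(self) -> dict:
        d = {
            "n_per_condition": self.n_per_condition,
            "conditions": list(self.conditions),
            "seed": self.seed,
            "sample_interval": self.sample_interval,
            "gender_balance": self.gender_balance,
            "spec_non_m": self.spec_non_m.tag,
            "params_non_m": _params_dict(self.params_non_m),
            "spec_m": self.spec_m.tag,
            "params_m": _params_dict(self.params_m),
            "crowd": asdict(self.crowd),
            "env_base": asdict(self.env_base),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDesign":
        d = dict(d)
        d["conditions"] = tuple(d["conditions"])
        d["spec_non_m"] = ModelSpec.from_tag(d["spec_non_m"])
        d["spec_m"] = ModelSpec.from_tag(d["spec_m"])
        d["params_non_m"] = ParameterVector.from_dict(d["params_non_m"])
        d["params_m"] = ParameterVector.from_dict(d["params_m"])
        d["crowd"] = CrowdParams(**d["crowd"])
        d["env_base"] = EnvironmentConfig(**d["env_base"])
        return cls(**d)


def _params_dict(p: ParameterVector) -> dict:
    return {k: v for k, v in asdict(p).items() if v is not None}


@dataclass
class Cohort:
    """Generated cohort: analysis inputs plus (separate) generating truth."""

    design: CohortDesign
    decisions: pd.DataFrame  # DecisionDataset rows, all participants
    outcomes: pd.DataFrame  # OutcomeTable frame (+ participant_id, condition)
    trajectories: dict  # participant_id -> ParticipantTrajectory
    histories: dict  # participant_id -> SimHistory
    n_regenerated: int = 0

    def decision_stratum(self, m_flag: bool) -> pd.DataFrame:
        cond_m = self.outcomes.set_index("participant_id")["M"]
        mask = self.decisions["participant_id"].map(cond_m) == m_flag
        return self.decisions.loc[mask].reset_index(drop=True)

    @property
    def mean_rows_per_participant(self) -> float:
        return float(self.decisions.groupby("participant_id").size().mean())


def _environment_for(design: CohortDesign, condition: str):
    from dataclasses import replace

    flags = condition_flags(condition)
    cfg = replace(design.env_base, exit_top_width=None, **flags)
    return build_environment(cfg)


def _one_participant(design, condition, env, pid, seeds, age, gender):
    """Simulate one participant's session; returns (traj, history, rows, summary)."""
    crowd_seed, ped_seed = seeds
    history = run_evacuation(env, design.crowd, seed=crowd_seed)
    m_active = condition_flags(condition)["treatment_M"]
    spec = design.spec_m if m_active else design.spec_non_m
    params = design.params_m if m_active else design.params_non_m
    traj = simulate_participant(
        history,
        spec,
        params,
        interval=design.sample_interval,
        seed=ped_seed,
        participant_id=pid,
        condition=condition,
        age=age,
        gender=gender,
    )
    if not traj.complete:
        raise RuntimeError("participant did not exit before the time cap")
    rows = sample_decision_points(traj, history, interval=design.sample_interval)
    summary = behavioural_summary(traj, env, n_samples=len(rows))
    return traj, history, rows, summary


def generate_cohort(design: CohortDesign, keep_histories: bool = True) -> Cohort:
    """Generate a full cohort from a design, reproducibly.

    Each participant gets an independently simulated crowd (fresh seed) and
    an independently seeded generative participant.  A participant whose
    simulation fails (e.g. time cap hit) is regenerated with a derived seed;
    the number of regenerations is recorded on the cohort.
    """
    ss = np.random.SeedSequence(design.seed)
    # three independent streams: demographics, crowd seeds, participant seeds
    demo_rng, seed_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    decision_frames = []
    outcome_rows = []
    trajectories = {}
    histories = {}
    n_regen = 0
    for condition in design.conditions:
        env = _environment_for(design, condition)
        for i in range(design.n_per_condition):
            pid = f"{condition}_{i:03d}"
            age = AGE_SHIFT + float(
                demo_rng.lognormal(mean=AGE_MU, sigma=AGE_SIGMA)
            )
            gender = int(demo_rng.random() < design.gender_balance)
            for attempt in range(5):
                seeds = [int(s) for s in seed_rng.integers(0, 2**31 - 1, size=2)]
                try:
                    traj, history, rows, summary = _one_participant(
                        design, condition, env, pid, seeds, age, gender
                    )
                    break
                except RuntimeError:
                    n_regen += 1
            else:
                raise RuntimeError(f"participant {pid} failed repeatedly")
            decision_frames.append(rows)
            flags = condition_flags(condition)
            outcome_rows.append(
                {
                    "participant_id": pid,
                    "condition": condition,
                    "S": flags["treatment_S"],
                    "W": flags["treatment_W"],
                    "M": flags["treatment_M"],
                    "age": age,
                    "gender": gender,
                    "chose_shortest": summary.chose_shortest,
                    "changed_mind": summary.changed_mind,
                    "n_samples": summary.n_samples,
                }
            )
            trajectories[pid] = traj
            if keep_histories:
                histories[pid] = history
    decisions = pd.concat(decision_frames, ignore_index=True)
    outcomes = pd.DataFrame(outcome_rows)
    return Cohort(
        design=design,
        decisions=decisions,
        outcomes=outcomes,
        trajectories=trajectories,
        histories=histories,
        n_regenerated=n_regen,
    )


def truth_report(cohort: Cohort) -> dict:
    """Generating truth plus realised summary statistics, for recovery tests.

    Raises if the cohort's truth has been stripped.
    """
    design = cohort.design
    if design.params_non_m is None or design.spec_non_m is None:
        raise ValueError("cohort carries no generating truth")
    outcomes = cohort.outcomes
    control = outcomes[outcomes["condition"] == "control"]
    return {
        "design": design.to_dict(),
        "generating": {
            "non_M": {"spec": design.spec_non_m.tag, "params": _params_dict(design.params_non_m)},
            "M": {"spec": design.spec_m.tag, "params": _params_dict(design.params_m)},
        },
        "realised": {
            "n_participants": int(len(outcomes)),
            "n_per_condition": {
                c: int((outcomes["condition"] == c).sum()) for c in design.conditions
            },
            "mean_rows_per_participant": cohort.mean_rows_per_participant,
            "target_rows_per_participant": 20.0,
            "p_shortest_control": float(control["chose_shortest"].mean()),
            "p_change_overall": float(outcomes["changed_mind"].mean()),
            "p_change_by_stratum": {
                "non_M": float(outcomes.loc[~outcomes["M"], "changed_mind"].mean()),
                "M": float(outcomes.loc[outcomes["M"], "changed_mind"].mean()),
            },
            "jammed_row_fraction": float((cohort.decisions["jam"] != 0).mean()),
            "n_regenerated": int(cohort.n_regenerated),
        },
    }


# ---------------------------------------------------------------------------
# cohort bundle serialisation (analysis files carry no truth fields)
# ---------------------------------------------------------------------------

TRUTH_SCHEMA_TAG = "exitchoice-truth-v1"


def write_cohort_bundle(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write a cohort bundle: config snapshot, truth file (schema-tagged,
    separate), trajectories CSV, decisions CSV, outcomes CSV.

    Returns a mapping of artefact name to path.  Analysis inputs contain no
    truth fields.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["decisions"] = out / "decisions.csv"
    cohort.decisions.to_csv(paths["decisions"], index=False)

    outcome_cols = [
        "participant_id", "condition", "S", "W", "M",
        "age", "gender", "chose_shortest", "changed_mind", "n_samples",
    ]
    paths["outcomes"] = out / "outcomes.csv"
    cohort.outcomes[outcome_cols].to_csv(paths["outcomes"], index=False)

    traj_rows = []
    for pid, traj in cohort.trajectories.items():
        for t, (x, y), pref in zip(traj.times, traj.positions, traj.preferred):
            traj_rows.append(
                {"participant_id": pid, "t_s": t, "x_m": x, "y_m": y, "preferred": pref}
            )
    paths["trajectories"] = out / "trajectories.csv"
    pd.DataFrame(traj_rows).to_csv(paths["trajectories"], index=False)

    truth = truth_report(cohort)
    truth["schema"] = TRUTH_SCHEMA_TAG
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=2))

    paths["design"] = out / "design.json"
    paths["design"].write_text(json.dumps(cohort.design.to_dict(), indent=2))
    return {k: str(v) for k, v in paths.items()}


def read_design(path: str | Path) -> CohortDesign:
    return CohortDesign.from_dict(json.loads(Path(path).read_text()))
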