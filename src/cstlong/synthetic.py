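"""Synthetic longitudinal vaginal-microbiome cohorts with known ground truth.

The generator emulates a two-group longitudinal 16S study: non-pregnant
subjects sampled twice weekly for 16 weeks (32 visits) and pregnant subjects
sampled every 4 gestational weeks to week 24 and every 2 weeks thereafter.
Each subject follows a first-order Markov chain over community state types
(CSTs); each visit's composition is drawn from a per-CST Dirichlet template;
read counts are zero-inflated negative binomial around depth x relative
abundance, with log-normal per-sample depth.  All generating parameters are
returned in a :class:`TruthRecord` so downstream estimators can be scored
against the truth.

The default scenario encodes the qualitative structure of a term-pregnancy
cohort: pregnant trajectories are more persistent and rarely enter the
anaerobe-dominated CSTs IV-A/IV-B, and four Lactobacillus phylotypes carry
positive group effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import CountTable

__all__ = [
    "CohortDesign",
    "Scenario",
    "TruthRecord",
    "default_scenario",
    "simulate_cst_markov",
    "simulate_cohort",
    "simulate_count_model",
]

CST_NAMES = ("I", "II", "III", "IV-A", "IV-B")

# 28 phylotypes: five vaginal Lactobacillus species, the genus-level pool,
# and the anaerobe taxa that characterise CST IV-A / IV-B.
DEFAULT_TAXA = (
    "Lactobacillus crispatus",
    "Lactobacillus gasseri",
    "Lactobacillus iners",
    "Lactobacillus jensenii",
    "Lactobacillus vaginalis",
    "Lactobacillus",
    "Gardnerella vaginalis",
    "Atopobium",
    "Atopobium vaginae",
    "Prevotella",
    "Prevotella bivia",
    "Sneathia",
    "Peptoniphilus",
    "Anaerococcus",
    "Anaerococcus vaginalis",
    "Corynebacterium",
    "Finegoldia magna",
    "Mobiluncus",
    "Parvimonas micra",
    "Ruminococcaceae",
    "Streptococcus anginosus",
    "Dialister",
    "Eggerthella",
    "Ureaplasma",
    "Megasphaera",
    "Aerococcus christensenii",
    "Clostridiales",
    "Bifidobacteriaceae",
)


def _twice_weekly(weeks: int = 16) -> tuple[float, ...]:
    return tuple(0.5 * k for k in range(1, 2 * weeks + 1))


def _prenatal(enroll: float = 8.0, switch: float = 24.0, end: float = 40.0) -> tuple[float, ...]:
    early = np.arange(enroll, switch + 1e-9, 4.0)
    late = np.arange(switch + 2.0, end + 1e-9, 2.0)
    return tuple(np.concatenate([early, late]))


@dataclass
class CohortDesign:
    """Study design: group sizes, per-group visit schedules, depth model, seed."""

    n_nonpregnant: int = 32
    n_pregnant: int = 22
    nonpregnant_schedule: tuple[float, ...] = field(default_factory=_twice_weekly)
    pregnant_schedule: tuple[float, ...] = field(default_factory=_prenatal)
    depth_median: float = 2878.0   # per-sample total reads, log-normal median
    depth_sigma: float = 0.55      # log-scale sd of the depth distribution
    dropout: float = 0.0           # per-visit probability a sample is missing
    seed: int = 0

    def __post_init__(self):
        if self.n_nonpregnant <= 0 or self.n_pregnant <= 0:
            raise ValueError("group sizes must be positive")
        for name in ("nonpregnant_schedule", "pregnant_schedule"):
            sched = np.asarray(getattr(self, name), dtype=float)
            if len(sched) == 0 or np.any(np.diff(sched) <= 0):
                raise ValueError(f"{name} must be non-empty and strictly increasing")
        if self.depth_median <= 0 or self.depth_sigma < 0:
            raise ValueError("invalid depth model")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def _check_stochastic(matrix: np.ndarray, name: str = "transition") -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{name} matrix must be square")
    if np.any(matrix < 0) or not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError(f"{name} matrix rows must be nonnegative and sum to 1")
    return matrix


def _default_templates() -> pd.DataFrame:
    """Per-CST Dirichlet mean compositions over the default 28 taxa."""
    taxa = list(DEFAULT_TAXA)
    t = pd.DataFrame(0.0, index=list(CST_NAMES), columns=taxa)
    rare = 0.002  # background share for taxa not named below

    def set_row(cst, named: dict[str, float]):
        t.loc[cst] = rare
        for taxon, share in named.items():
            t.loc[cst, taxon] = share
        t.loc[cst] /= t.loc[cst].sum()

    set_row("I", {"Lactobacillus crispatus": 0.78, "Lactobacillus": 0.08,
                  "Lactobacillus iners": 0.04, "Lactobacillus jensenii": 0.02,
                  "Lactobacillus vaginalis": 0.015})
    set_row("II", {"Lactobacillus gasseri": 0.75, "Lactobacillus": 0.09,
                   "Lactobacillus iners": 0.04, "Lactobacillus vaginalis": 0.02})
    set_row("III", {"Lactobacillus iners": 0.77, "Lactobacillus": 0.08,
                    "Gardnerella vaginalis": 0.03, "Lactobacillus jensenii": 0.02})
    # IV-A: roughly even anaerobes, little Atopobium
    set_row("IV-A", {"Peptoniphilus": 0.14, "Anaerococcus": 0.13,
                     "Corynebacterium": 0.12, "Finegoldia magna": 0.12,
                     "Prevotella": 0.13, "Anaerococcus vaginalis": 0.08,
                     "Streptococcus anginosus": 0.06, "Ruminococcaceae": 0.05,
                     "Dialister": 0.04, "Lactobacillus iners": 0.04})
    # IV-B: Atopobium-weighted with Gardnerella, low L. iners
    set_row("IV-B", {"Atopobium": 0.28, "Atopobium vaginae": 0.10,
                     "Gardnerella vaginalis": 0.16, "Lactobacillus iners": 0.08,
                     "Prevotella": 0.07, "Prevotella bivia": 0.04,
                     "Sneathia": 0.06, "Parvimonas micra": 0.04,
                     "Mobiluncus": 0.03, "Megasphaera": 0.04,
                     "Eggerthella": 0.03, "Ruminococcaceae": 0.03})
    return t


def _persistence_matrix(stay: float, mix: np.ndarray) -> np.ndarray:
    """Markov matrix: probability ``stay`` of persisting, else move per ``mix``."""
    k = len(mix)
    out = np.zeros((k, k))
    for i in range(k):
        off = mix.copy()
        off[i] = 0.0
        off = off / off.sum()
        out[i] = (1.0 - stay) * off
        out[i, i] = stay
    return out


@dataclass
class Scenario:
    """Group-specific CST dynamics, composition templates, and taxon effects."""

    taxa: tuple[str, ...]
    cst_names: tuple[str, ...]
    templates: pd.DataFrame                 # cst x taxa Dirichlet means
    concentration: float                    # Dirichlet precision (higher = tighter)
    transition: dict[str, np.ndarray]       # group -> k x k stochastic matrix
    initial: dict[str, np.ndarray]          # group -> length-k distribution
    beta_true: pd.Series                    # per-taxon group (pregnant) log-fold effect
    pi_true: pd.Series                      # per-taxon zero-inflation probability
    theta: float = 3.0                      # NB size (dispersion) parameter
    # P(high Nugent >= 7 | CST)
    nugent_high_prob: dict[str, float] = field(
        default_factory=lambda: {"I": 0.01, "II": 0.02, "III": 0.05, "IV-A": 0.30, "IV-B": 0.85})

    def __post_init__(self):
        self.templates = self.templates.loc[list(self.cst_names), list(self.taxa)]
        if (self.templates.to_numpy() <= 0).any():
            raise ValueError("Dirichlet template means must be positive")
        if self.concentration <= 0 or self.theta <= 0:
            raise ValueError("concentration and theta must be positive")
        for g, m in self.transition.items():
            self.transition[g] = _check_stochastic(m, f"{g} transition")
        for g, v in self.initial.items():
            v = np.asarray(v, dtype=float)
            if np.any(v < 0) or not np.isclose(v.sum(), 1.0, atol=1e-8):
                raise ValueError(f"{g} initial distribution must sum to 1")
            self.initial[g] = v
        self.beta_true = self.beta_true.reindex(list(self.taxa)).fillna(0.0)
        self.pi_true = self.pi_true.reindex(list(self.taxa)).fillna(0.0)
        if ((self.pi_true < 0) | (self.pi_true >= 1)).any():
            raise ValueError("pi_true must lie in [0, 1)")


def default_scenario(
    pregnant_iv_entry: float | None = None,
    beta_overrides: dict[str, float] | None = None,
    concentration: float = 150.0,
) -> Scenario:
    """The default study conditions.

    Non-pregnant chains persist with probability 0.90 per visit and visit the
    anaerobe CSTs regularly; pregnant chains persist with probability 0.96
    and enter CST IV-A/IV-B only rarely (entry mass ``pregnant_iv_entry``,
    default 0.004 per off-diagonal step).  Four Lactobacillus phylotypes
    carry the positive pregnancy effects seen in term cohorts; the anaerobe
    taxa carry zero direct effect (their depletion arises from CST occupancy).
    """
    k = len(CST_NAMES)
    # where a chain goes when it moves (I, II, III, IV-A, IV-B)
    np_mix = np.array([0.22, 0.10, 0.33, 0.12, 0.23])
    preg_mix = np.array([0.40, 0.10, 0.46, 0.02, 0.02])
    if pregnant_iv_entry is not None:
        preg_mix = np.array([0.0, 0.0, 0.0, 0.5, 0.5]) * pregnant_iv_entry * 2
        lacto = 1.0 - preg_mix.sum()
        preg_mix += np.array([0.45, 0.10, 0.45, 0.0, 0.0]) * lacto
    transition = {
        "non_pregnant": _persistence_matrix(0.90, np_mix),
        "pregnant": _persistence_matrix(0.96, preg_mix),
    }
    initial = {
        # occupancy in line with observed sample distributions by group
        "non_pregnant": np.array([0.17, 0.09, 0.35, 0.10, 0.29]),
        "pregnant": np.array([0.38, 0.05, 0.51, 0.04, 0.02]),
    }
    beta = pd.Series(0.0, index=list(DEFAULT_TAXA))
    beta["Lactobacillus jensenii"] = 1.549
    beta["Lactobacillus vaginalis"] = 1.704
    beta["Lactobacillus crispatus"] = 0.754
    beta["Lactobacillus gasseri"] = 1.193
    if beta_overrides:
        for taxon, b in beta_overrides.items():
            beta[taxon] = b
    pi = pd.Series(0.0, index=list(DEFAULT_TAXA))
    for taxon in ("Lactobacillus vaginalis", "Atopobium", "Eggerthella",
                  "Gardnerella vaginalis", "Parvimonas micra", "Aerococcus christensenii"):
        pi[taxon] = 0.35
    return Scenario(
        taxa=tuple(DEFAULT_TAXA),
        cst_names=tuple(CST_NAMES),
        templates=_default_templates(),
        concentration=concentration,
        transition=transition,
        initial=initial,
        beta_true=beta,
        pi_true=pi,
    )


@dataclass
class TruthRecord:
    """Generating parameters and latent states of one simulated cohort."""

    cst_trajectories: dict[str, list[str]]      # subject -> CST label per visit
    transition: dict[str, np.ndarray]
    templates: pd.DataFrame
    beta_true: pd.Series
    pi_true: pd.Series
    theta: float
    concentration: float

    def to_json(self, path) -> None:
        payload = {
            "cst_trajectories": self.cst_trajectories,
            "transition": {g: m.tolist() for g, m in self.transition.items()},
            "templates": self.templates.to_dict(orient="index"),
            "beta_true": self.beta_true.to_dict(),
            "pi_true": self.pi_true.to_dict(),
            "theta": self.theta,
            "concentration": self.concentration,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_cst_markov(
    transition: np.ndarray,
    initial: np.ndarray,
    n_steps: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Sample a CST index trajectory of length ``n_steps`` from a Markov chain."""
    transition = _check_stochastic(transition)
    initial = np.asarray(initial, dtype=float)
    if np.any(initial < 0) or not np.isclose(initial.sum(), 1.0, atol=1e-8):
        raise ValueError("initial distribution must be nonnegative and sum to 1")
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    k = transition.shape[0]
    out = np.empty(n_steps, dtype=np.int64)
    out[0] = rng.choice(k, p=initial)
    for t in range(1, n_steps):
        out[t] = rng.choice(k, p=transition[out[t - 1]])
    return out


def _zinb_counts(mean: np.ndarray, theta: float, pi: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Zero-inflated NB draws, mean/size parameterisation, elementwise pi."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    counts = rng.poisson(lam)
    zeros = rng.random(mean.shape) < pi
    counts[zeros] = 0
    return counts


def simulate_cohort(design: CohortDesign, scenario: Scenario | None = None
                    ) -> tuple[CountTable, TruthRecord]:
    """Generate one longitudinal cohort and its ground truth.

    Each subject's CST trajectory is Markov; each visit draws a composition
    from the visit CST's Dirichlet template (pregnant compositions tilted by
    exp(beta_true) per taxon, renormalised), then counts are ZINB around
    depth x composition with NB size ``scenario.theta``.
    """
    scenario = scenario or default_scenario()
    rng = np.random.default_rng(design.seed)
    taxa = list(scenario.taxa)
    alpha = scenario.templates.to_numpy() * scenario.concentration  # cst x taxa
    tilt = np.exp(scenario.beta_true.to_numpy())
    pi = scenario.pi_true.to_numpy()

    rows, meta_rows, trajectories = [], [], {}
    specs = [("NP", "non_pregnant", design.n_nonpregnant, design.nonpregnant_schedule),
             ("P", "pregnant", design.n_pregnant, design.pregnant_schedule)]
    for prefix, group, n_subjects, schedule in specs:
        trans = scenario.transition[group]
        init = scenario.initial[group]
        for s in range(n_subjects):
            subject = f"{prefix}{s + 1:03d}"
            states = simulate_cst_markov(trans, init, len(schedule), rng)
            labels = [scenario.cst_names[i] for i in states]
            kept_labels = []
            for visit, (week, cst_idx) in enumerate(zip(schedule, states)):
                if design.dropout and rng.random() < design.dropout:
                    continue
                kept_labels.append(scenario.cst_names[cst_idx])
                comp = rng.dirichlet(alpha[cst_idx])
                if group == "pregnant":
                    comp = comp * tilt
                    comp /= comp.sum()
                depth = rng.lognormal(np.log(design.depth_median), design.depth_sigma)
                counts = _zinb_counts(depth * comp, scenario.theta, pi, rng)
                cst = scenario.cst_names[cst_idx]
                if rng.random() < scenario.nugent_high_prob.get(cst, 0.05):
                    nugent = int(rng.integers(7, 11))
                else:
                    nugent = int(rng.integers(0, 5))
                rows.append((f"{subject}_v{visit + 1:02d}", counts))
                meta_rows.append((f"{subject}_v{visit + 1:02d}", subject, group,
                                  float(week), nugent, cst))
            trajectories[subject] = kept_labels if design.dropout else labels

    counts = pd.DataFrame(
        np.vstack([c for _, c in rows]).astype(np.int64),
        index=[sid for sid, _ in rows], columns=taxa)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "subject_id", "group", "week",
                            "nugent", "true_cst"]).set_index("sample_id")
    table = CountTable(counts, metadata).drop_empty_samples()
    truth = TruthRecord(
        cst_trajectories=trajectories,
        transition={g: m.copy() for g, m in scenario.transition.items()},
        templates=scenario.templates.copy(),
        beta_true=scenario.beta_true.copy(),
        pi_true=scenario.pi_true.copy(),
        theta=scenario.theta,
        concentration=scenario.concentration,
    )
    return table, truth


def simulate_count_model(
    family: str,
    n_subjects: int,
    n_visits: int,
    beta0: float,
    beta1: float,
    sigma_b: float,
    theta: float = 3.0,
    pi: float = 0.0,
    depth_median: float = 2878.0,
    depth_sigma: float = 0.55,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one phylotype's counts directly from a PLME/NBLME/ZINBLME model.

    Half the subjects are assigned to each group.  The log mean is
    ``beta0 + beta1 * group + b_subject + log(total reads)`` with
    b_subject ~ Normal(0, sigma_b^2); this is the exact likelihood the
    count-model fitters maximise, so it serves as the parameter-recovery
    oracle.  Returns a long DataFrame (y, group, subject, total).
    """
    if family not in ("PLME", "NBLME", "ZINBLME"):
        raise ValueError(f"unknown family {family!r}")
    if family != "ZINBLME" and pi != 0.0:
        raise ValueError("pi is a ZINBLME parameter")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    rows = []
    for s in range(n_subjects):
        group = int(s >= n_subjects // 2)
        b = rng.normal(0.0, sigma_b)
        for v in range(n_visits):
            total = max(int(rng.lognormal(np.log(depth_median), depth_sigma)), 50)
            mu = np.exp(beta0 + beta1 * group + b + np.log(total))
            if family == "PLME":
                y = rng.poisson(mu)
            else:
                lam = rng.gamma(shape=theta, scale=mu / theta)
                y = rng.poisson(lam)
                if family == "ZINBLME" and rng.random() < pi:
                    y = 0
            rows.append((y, group, f"S{s:03d}", total))
    return pd.DataFrame(rows, columns=["y", "group", "subject", "total"])
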