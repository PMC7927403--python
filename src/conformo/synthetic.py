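"""Synthetic ground-truth data for every pipeline stage.

Nothing here emulates full MD physics or all-atom structures; the goal is
minimal data with *known truth* so each analysis stage can be validated
end-to-end: two-helix C-alpha scaffolds with a prescribed Val84-Leu249
distance, mean-reverting (Ornstein-Uhlenbeck) descriptor trajectories that
drift toward the active- or inactive-state distance after an annealing
period, median-matched Gaussian docking-score classes, and noisy assay
curves drawn from the exact models the fitting module implements.

Every generator is a pure function of its spec (seed included) and returns
a truth record sufficient to compute any downstream expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .pharmacology import association_dissociation, logistic_3pl
from .screening import ScoreSet
from .structio import ResiduePairDescriptor, StructureModel
from .trajectory import DistanceSeries

# Published descriptor values used as generator defaults: the active/inactive
# A2AR crystal forms separate at 14.53 A (widest, adenosine-bound) versus
# 12.96 A (narrowest, antagonist-bound).
ACTIVE_DISTANCE = 14.53
INACTIVE_DISTANCE = 12.96

#: Synthetic stand-in for the per-structure descriptor table of the 14 A2AR
#: crystal forms. Only the range endpoints are published (actives span
#: 14.30-14.53 A, inactives 12.96-13.36 A, extremes 2YDO and 5IU4); the
#: interior values are evenly interpolated placeholders, not measurements.
SYNTHETIC_REFERENCE_DISTANCES: dict[str, tuple[str, float]] = {
    "2YDO": ("active", 14.53),
    "4UHR": ("active", 14.47),
    "2YDV": ("active", 14.41),
    "4UG2": ("active", 14.35),
    "3QAK": ("active", 14.30),
    "5IU4": ("inactive", 12.96),
    "3UZA": ("inactive", 13.01),
    "5K2A": ("inactive", 13.06),
    "4EIY": ("inactive", 13.11),
    "3EML": ("inactive", 13.16),
    "5NM2": ("inactive", 13.21),
    "5JTB": ("inactive", 13.26),
    "5UVI": ("inactive", 13.31),
    "5UIG": ("inactive", 13.36),
}

_HELIX_RADIUS = 2.3  # A
_HELIX_RISE = 1.5  # A per residue
_HELIX_TWIST = math.radians(100.0)
_TM3_RESIDUES = tuple(range(75, 90))  # contains Val84
_TM6_RESIDUES = tuple(range(242, 257))  # contains Leu249


@dataclass(frozen=True)
class TwoStateEnsembleSpec:
    n_active: int = 5
    n_inactive: int = 9
    active_distance: float = ACTIVE_DISTANCE
    inactive_distance: float = INACTIVE_DISTANCE
    #: per-axis coordinate jitter; 0.25 A makes the per-residue scatter
    #: (~ sigma * sqrt(2.5) under the pair-distance constraint) match the
    #: ~0.4 A heterogeneity seen across the real crystal forms
    jitter_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.active_distance <= self.inactive_distance:
            raise ValueError("active_distance must exceed inactive_distance")
        if min(self.active_distance, self.inactive_distance) <= 0:
            raise ValueError("distances must be positive")


@dataclass(frozen=True)
class TrajectorySpec:
    state_target: str = "active"  # {active, inactive, apo}
    start_distance: float = INACTIVE_DISTANCE
    target_distance: float = ACTIVE_DISTANCE
    anneal_ns: float = 50.0
    total_ns: float = 500.0
    frame_interval_ns: float = 0.1
    reversion_rate: float = 0.05  # 1/ns (tau = 20 ns)
    #: chosen so the OU stationary s.d. is 0.4 A: sigma = 0.4*sqrt(2*rate)
    noise_sigma: float = 0.4 * math.sqrt(2 * 0.05)  # A / sqrt(ns)
    seed: int = 0

    def __post_init__(self):
        if self.total_ns <= self.anneal_ns:
            raise ValueError("total_ns must exceed anneal_ns")
        if self.reversion_rate <= 0 or self.noise_sigma < 0:
            raise ValueError("reversion_rate must be positive, noise_sigma non-negative")


@dataclass(frozen=True)
class ScoreSetSpec:
    #: class label -> (n, median, spread); defaults mirror the screen's
    #: published class sizes (39/38/133) and score medians
    classes: tuple[tuple[str, int, float, float], ...] = (
        ("agonist", 39, -11.24, 1.5),
        ("antagonist", 38, -7.88, 1.5),
        ("inactive", 133, -6.74, 1.5),
    )
    seed: int = 0

    def __post_init__(self):
        for label, n, _median, spread in self.classes:
            if n < 1 or spread <= 0:
                raise ValueError(f"class {label}: need n >= 1 and spread > 0")


@dataclass(frozen=True)
class AssayCurveSpec:
    model: str = "3pl"  # {3pl, competition, assoc_dissoc}
    params: tuple[tuple[str, float], ...] = (("basal", 0.0), ("emax", 100.0), ("pec50", 7.0))
    noise_sigma: float = 5.0  # additive, response-% units
    n_points: int = 10
    n_replicates: int = 3
    seed: int = 0

    def param_dict(self) -> dict[str, float]:
        return dict(self.params)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _base_scaffold(pair_distance: float) -> dict[int, np.ndarray]:
    """Two idealised antiparallel helices with the exact descriptor distance.

    TM3-like helix at the origin, TM6-like helix offset along +x so that the
    C-alpha atoms of residues 84 and 249 sit ``pair_distance`` apart.
    """
    coords: dict[int, np.ndarray] = {}
    for k, res in enumerate(_TM3_RESIDUES):
        phi = _HELIX_TWIST * k
        coords[res] = np.array(
            [_HELIX_RADIUS * math.cos(phi), _HELIX_RADIUS * math.sin(phi), _HELIX_RISE * k]
        )
    tm6: dict[int, np.ndarray] = {}
    for k, res in enumerate(_TM6_RESIDUES):
        phi = _HELIX_TWIST * k + 0.5
        tm6[res] = np.array(
            [_HELIX_RADIUS * math.cos(phi), _HELIX_RADIUS * math.sin(phi), _HELIX_RISE * (len(_TM6_RESIDUES) - 1 - k)]
        )
    v = tm6[249] - coords[84]
    rest = pair_distance**2 - v[1] ** 2 - v[2] ** 2
    if rest <= 0:
        raise ValueError(f"pair_distance {pair_distance} too small for the scaffold geometry")
    dx = -v[0] + math.sqrt(rest)
    for res, xyz in tm6.items():
        coords[res] = xyz + np.array([dx, 0.0, 0.0])
    return coords


def _constrain_pair(coords: dict[int, np.ndarray], pair_distance: float) -> None:
    """Rescale the 84-249 separation about its midpoint to the exact value."""
    u = coords[249] - coords[84]
    mid = 0.5 * (coords[249] + coords[84])
    u *= pair_distance / np.linalg.norm(u)
    coords[84] = mid - 0.5 * u
    coords[249] = mid + 0.5 * u


def _random_rigid_motion(coords: dict[int, np.ndarray], rng: np.random.Generator) -> dict[int, np.ndarray]:
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-20.0, 20.0, size=3)
    return {r: rot @ xyz + trans for r, xyz in coords.items()}


def build_model(
    structure_id: str,
    state: str,
    pair_distance: float,
    jitter_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    exact_pair: bool = True,
    rigid_motion: bool = True,
) -> StructureModel:
    """One synthetic C-alpha model on the 30-residue two-helix scaffold.

    With ``exact_pair`` the Val84-Leu249 distance is held exactly at
    ``pair_distance`` after jittering (the jitter component along the
    separation axis is projected out); otherwise the jitter perturbs the
    distance too.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    coords = _base_scaffold(pair_distance)
    if jitter_sigma > 0:
        for res in coords:
            coords[res] = coords[res] + rng.normal(0.0, jitter_sigma, size=3)
        if exact_pair:
            _constrain_pair(coords, pair_distance)
    if rigid_motion:
        coords = _random_rigid_motion(coords, rng)
    return StructureModel(structure_id, "A", coords, state)


def make_ensemble(spec: TwoStateEnsembleSpec) -> tuple[list[StructureModel], pd.DataFrame]:
    """Two-state ensemble with per-model truth distances.

    Models are named ACT01.., INA01..; the truth table records the target
    and the realised (measured) descriptor distance of every member.
    """
    from .structio import pair_distance as _measure

    rng = np.random.default_rng(spec.seed)
    models, rows = [], []
    plan = [("ACT%02d" % (i + 1), "active", spec.active_distance) for i in range(spec.n_active)]
    plan += [("INA%02d" % (i + 1), "inactive", spec.inactive_distance) for i in range(spec.n_inactive)]
    for sid, state, target in plan:
        m = build_model(sid, state, target, spec.jitter_sigma, rng, exact_pair=False)
        d = _measure(m, ResiduePairDescriptor())
        models.append(m)
        rows.append({"structure_id": sid, "state": state, "target_distance": target, "distance": d})
    return models, pd.DataFrame(rows)


def make_reference_ensemble(
    seed: int = 0, jitter_sigma: float = 0.25
) -> tuple[list[StructureModel], pd.DataFrame]:
    """Synthetic stand-in for the 14-structure A2AR crystal ensemble.

    Each member's descriptor distance is held exactly at the value in
    ``SYNTHETIC_REFERENCE_DISTANCES`` while all residues (the descriptor pair
    included) carry positional jitter, emulating an ensemble that is
    heterogeneous residue-by-residue yet has known descriptor values.
    """
    rng = np.random.default_rng(seed)
    models, rows = [], []
    for sid, (state, dist) in SYNTHETIC_REFERENCE_DISTANCES.items():
        m = build_model(sid, state, dist, jitter_sigma, rng, exact_pair=True)
        models.append(m)
        rows.append({"structure_id": sid, "state": state, "distance": dist})
    return models, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def make_trajectory(spec: TrajectorySpec) -> tuple[DistanceSeries, dict]:
    """Euler-Maruyama mean-reverting descriptor series.

    During annealing the process reverts to the start distance; afterwards
    the target switches to the forced-state distance, so agonist-forced runs
    drift from the inactive toward the active descriptor value.
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.frame_interval_ns
    n = int(round(spec.total_ns / dt))
    out = np.empty(n)
    d = spec.start_distance
    sqdt = math.sqrt(dt)
    eps = rng.standard_normal(n)
    for i in range(n):
        t = (i + 1) * dt
        target = spec.start_distance if t <= spec.anneal_ns else spec.target_distance
        d = d + spec.reversion_rate * (target - d) * dt + spec.noise_sigma * sqdt * eps[i]
        out[i] = d
    series = DistanceSeries(
        label=spec.state_target,
        frame_interval_ns=dt,
        distances=out,
        anneal_ns=spec.anneal_ns,
    )
    # AR(1) stationary s.d. implied by the discretisation
    phi = 1.0 - spec.reversion_rate * dt
    stat_var = spec.noise_sigma**2 * dt / (1.0 - phi**2) if spec.noise_sigma > 0 else 0.0
    truth = {
        "spec": spec,
        "stationary_sd": math.sqrt(stat_var),
        "start_distance": spec.start_distance,
        "target_distance": spec.target_distance,
    }
    return series, truth


def agonist_trajectory_spec(seed: int = 0, **kw) -> TrajectorySpec:
    return TrajectorySpec(state_target="active", start_distance=INACTIVE_DISTANCE,
                          target_distance=ACTIVE_DISTANCE, seed=seed, **kw)


def antagonist_trajectory_spec(seed: int = 0, **kw) -> TrajectorySpec:
    return TrajectorySpec(state_target="inactive", start_distance=INACTIVE_DISTANCE,
                          target_distance=INACTIVE_DISTANCE, seed=seed, **kw)


def make_trajectory_frames(
    distances: Sequence[float], seed: int = 0
) -> tuple[list[StructureModel], np.ndarray]:
    """Scaffold frames whose descriptor values equal ``distances`` exactly."""
    rng = np.random.default_rng(seed)
    frames = [
        build_model(f"frame{i:04d}", "unknown", float(d), 0.0, rng, rigid_motion=True)
        for i, d in enumerate(distances)
    ]
    return frames, np.asarray(distances, dtype=float)


# ---------------------------------------------------------------------------
# Docking scores
# ---------------------------------------------------------------------------

def make_scores(spec: ScoreSetSpec = ScoreSetSpec()) -> tuple[dict[str, ScoreSet], pd.DataFrame]:
    """Per-class Gaussian scores, shifted so sample medians match exactly."""
    rng = np.random.default_rng(spec.seed)
    sets: dict[str, ScoreSet] = {}
    rows = []
    for label, n, median, spread in spec.classes:
        draws = rng.normal(median, spread, size=n)
        draws += median - np.median(draws)  # post-hoc median correction
        entries = [(f"{label[:4]}{i + 1:03d}", float(s)) for i, s in enumerate(draws)]
        sets[label] = ScoreSet(label if label in ("agonist", "antagonist", "inactive", "candidate") else "candidate", entries)
        rows.append({"class": label, "n": n, "requested_median": median, "realised_median": float(np.median(draws))})
    return sets, pd.DataFrame(rows)


def synthetic_candidate_scores() -> ScoreSet:
    """Synthetic stand-in for the 11 candidate compounds of the screen.

    The individual docking scores were never published; these are fabricated
    values constructed so that exactly six fall below the -7.33 agonist
    threshold, mirroring the published shortlist size.
    """
    entries = [
        ("cand01", -9.12), ("cand02", -8.91), ("cand03", -8.47), ("cand04", -8.05),
        ("cand05", -7.61), ("cand06", -7.40), ("cand07", -7.21), ("cand08", -6.88),
        ("cand09", -6.31), ("cand10", -5.94), ("cand11", -5.02),
    ]
    return ScoreSet("candidate", entries)


# ---------------------------------------------------------------------------
# Assays
# ---------------------------------------------------------------------------

_LOG_GRID = {"3pl": (-10.0, -4.0), "competition": (-11.0, -4.0)}


def make_assay(spec: AssayCurveSpec) -> tuple[pd.DataFrame, dict]:
    """Noisy assay table drawn from the requested generating model.

    3pl / competition specs evaluate the dose-response or displacement model
    on a half-log concentration grid; assoc_dissoc evaluates the kinetic
    trace on a uniform time grid (params: beq, kobs, koff, injection_time)
    and returns (time_min, signal) columns instead of concentrations.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.param_dict()
    if spec.model == "3pl":
        lo, hi = _LOG_GRID["3pl"]
        logc = np.linspace(lo, hi, spec.n_points)
        conc = 10.0**logc
        clean = logistic_3pl(conc, p["basal"], p["emax"], p["pec50"])
    elif spec.model == "competition":
        lo, hi = _LOG_GRID["competition"]
        logc = np.linspace(lo, hi, spec.n_points)
        conc = 10.0**logc
        # descending unit-slope displacement; IC50 back-computed from pKi
        ic50 = 10.0 ** (-p["pki"]) * (1.0 + p["hot_conc"] / p["hot_kd"])
        clean = p["bottom"] + (p["top"] - p["bottom"]) / (1.0 + conc / ic50)
    elif spec.model == "assoc_dissoc":
        t = np.linspace(0.0, p.get("t_end", 50.0), spec.n_points)
        clean = association_dissociation(t, p["beq"], p["kobs"], p["koff"], p["injection_time"])
        rows = []
        for rep in range(1, spec.n_replicates + 1):
            noisy = clean + rng.normal(0.0, spec.noise_sigma, size=clean.size)
            rows.append(pd.DataFrame({"time_min": t, "signal": noisy, "replicate": rep}))
        return pd.concat(rows, ignore_index=True), {"spec": spec, "params": p, "clean": clean, "time_min": t}
    else:
        raise ValueError(f"unknown assay model {spec.model!r}")
    rows = []
    for rep in range(1, spec.n_replicates + 1):
        noisy = clean + rng.normal(0.0, spec.noise_sigma, size=clean.size)
        rows.append(
            pd.DataFrame(
                {
                    "compound_id": "cmpd",
                    "cell_context": "synthetic",
                    "conc_M": conc,
                    "response_pct": noisy,
                    "replicate": rep,
                }
            )
        )
    return pd.concat(rows, ignore_index=True), {"spec": spec, "params": p, "clean": clean, "conc_M": conc}


def make_correlated_potency_panel(
    n_compounds: int = 16,
    rho: float = 0.80,
    seed: int = 0,
    noise_sigma: float = 5.0,
) -> tuple[list[tuple[pd.DataFrame, pd.DataFrame]], pd.DataFrame]:
    """Per-compound paired cAMP / proliferation assay tables.

    True cAMP pEC50 and anti-proliferation pIC50 are drawn from a bivariate
    normal with correlation ``rho`` (means 6.5 / 5.5, s.d. 0.8), then each
    compound gets one noisy stimulatory 3PL curve and one descending
    proliferation curve. The truth table lists the generating potencies.
    """
    rng = np.random.default_rng(seed)
    cov = 0.8**2 * np.array([[1.0, rho], [rho, 1.0]])
    potencies = rng.multivariate_normal([6.5, 5.5], cov, size=n_compounds)
    tables, rows = [], []
    for i, (pec50, pic50) in enumerate(potencies):
        camp_spec = AssayCurveSpec(
            model="3pl", params=(("basal", 5.0), ("emax", 90.0), ("pec50", float(pec50))),
            noise_sigma=noise_sigma, seed=int(rng.integers(0, 2**31 - 1)),
        )
        prolif_spec = AssayCurveSpec(
            model="3pl", params=(("basal", 100.0), ("emax", 35.0), ("pec50", float(pic50))),
            noise_sigma=noise_sigma, seed=int(rng.integers(0, 2**31 - 1)),
        )
        camp, _ = make_assay(camp_spec)
        prolif, _ = make_assay(prolif_spec)
        tables.append((camp, prolif))
        rows.append({"compound": f"cmpd{i + 1:02d}", "true_pec50": pec50, "true_pic50": pic50})
    return tables, pd.DataFrame(rows)
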