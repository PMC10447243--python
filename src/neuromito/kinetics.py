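"""Reduced kinetic model of neuronal mitochondrial ATP production.

The network deliberately collapses mitochondrial energy metabolism to the
smallest set of reactions that still supports the three contracts this
package needs:

* **proteomic scaling** — every enzymatic maximal rate is multiplied by the
  relative abundance (sample / control mean) of the proteins mapped to it,
  ``v_max(case) = v_max(normal) x E(case)/E(mean control)``;
* **metabolic load titration** — ATP consumption follows the hyperbolic law
  ``v_ATP = k_load x ATP/(ATP + K_m)`` and ``k_load`` is raised in steps
  until the ATP production rate converges to its maximum;
* **in-silico rectification** — groups of enzyme abundances (TCA cycle,
  electron transport chain) can be reset to control levels and the model
  re-run to ask which group limits ATP the most.

Network (state variables S, M1, M2, NADH, NAD, ATP, ADP and the inner-
membrane potential dpsi in mV):

    supply:    -> S                      (saturable substrate inflow)
    tca_a:     S   + NAD -> M1 + NADH    (Idh3 segment, NADH-producing)
    tca_b:     M1        -> M2           (Ogdh/Sdh segment)
    tca_c:     M2  + NAD ->    + NADH    (Mdh2 segment, NADH-producing)
    etc:       NADH -> NAD, pumps n_pump protons  (complexes I-IV lump)
    synthase:  ADP -> ATP, consumes n_syn protons (complex V)
    leak:      proton leak, saturating dpsi dependence
    load:      ATP -> ADP at v_ATP = k_load * ATP/(ATP + K_m_load)

Proton fluxes integrate into dpsi through an effective capacitance, so the
membrane potential couples respiration to phosphorylation.  ATP+ADP and
NADH+NAD are conserved by construction of the stoichiometry; both pools
are integrated explicitly so conservation is a property of the solved
system, not an algebraic substitution.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

STATE_NAMES = ("S", "M1", "M2", "NADH", "NAD", "ATP", "ADP", "psi")

#: reference parameterisation: concentrations mM, time s, potential mV.
DEFAULT_CONFIG: dict = {
    "pools": {"A_total": 3.0, "NAD_total": 0.5},
    "initial": {"S": 0.2, "M1": 0.1, "M2": 0.1, "NADH_fraction": 0.3,
                "ATP_fraction": 0.5, "psi": 150.0},
    "membrane": {"c_mem": 0.05, "n_pump": 10.0, "n_syn": 3.0},
    "reactions": {
        "supply": {"vmax": 0.3, "K_i": 0.5},
        "tca_a": {"vmax": 0.5, "K_S": 0.5, "K_NAD": 0.1},
        "tca_b": {"vmax": 0.5, "K_M1": 0.5},
        "tca_c": {"vmax": 0.5, "K_M2": 0.5, "K_NAD": 0.1},
        "etc": {"vmax": 1.2, "K_NADH": 0.15, "psi_max": 170.0, "psi_slope": 8.0},
        "synthase": {"vmax": 1.2, "K_ADP": 0.4, "psi_half": 130.0,
                     "psi_slope": 8.0},
        "leak": {"vmax": 2.5, "K_psi": 120.0},
        "load": {"k_load": 0.6, "K_m": 0.5},
    },
    "protein_map": {
        "tca_a": ["Idh3a", "Idh3b", "Idh3g"],
        "tca_b": ["Ogdh", "Sdha"],
        "tca_c": ["Mdh2"],
        "etc": ["Ndufs1", "Ndufv1", "Sdhb", "Uqcrc1", "Uqcrc2", "Cox4i1",
                "Cox5a"],
        "synthase": ["Atp5f1a", "Atp5f1b"],
    },
}

#: default protein groups for rectification experiments
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "TCA": ("Idh3a", "Idh3b", "Idh3g", "Ogdh", "Sdha", "Mdh2"),
    "ETC": ("Ndufs1", "Ndufv1", "Sdhb", "Uqcrc1", "Uqcrc2", "Cox4i1",
            "Cox5a", "Atp5f1a", "Atp5f1b"),
}


@dataclass
class KineticModel:
    """Reaction network with parameters, pools and a protein-to-reaction map."""

    config: dict
    protein_map: dict[str, list[str]]
    redundant_isoforms: dict[str, list[list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"pools", "initial", "membrane", "reactions"}
        missing = required - set(self.config)
        if missing:
            raise ValueError(f"config missing sections: {sorted(missing)}")
        rx = self.config["reactions"]
        for rid, params in rx.items():
            for key, val in params.items():
                if key.startswith(("vmax", "K", "k_")) and val <= 0:
                    raise ValueError(f"reaction {rid!r}: {key} must be > 0")
        for pool, val in self.config["pools"].items():
            if val <= 0:
                raise ValueError(f"pool {pool} must be > 0")
        for rid in self.protein_map:
            if rid not in rx:
                raise ValueError(f"protein map references unknown reaction {rid!r}")
            if not self.protein_map[rid]:
                raise ValueError(f"scalable reaction {rid!r} has no mapped proteins")

    # -- construction ----------------------------------------------------
    def copy(self) -> "KineticModel":
        return KineticModel(
            copy.deepcopy(self.config),
            copy.deepcopy(self.protein_map),
            copy.deepcopy(self.redundant_isoforms),
        )

    def mapped_proteins(self) -> set[str]:
        return {p for ps in self.protein_map.values() for p in ps}

    # -- dynamics --------------------------------------------------------
    def initial_state(self) -> np.ndarray:
        ini = self.config["initial"]
        pools = self.config["pools"]
        nadh = ini["NADH_fraction"] * pools["NAD_total"]
        atp = ini["ATP_fraction"] * pools["A_total"]
        return np.array([
            ini["S"], ini["M1"], ini["M2"],
            nadh, pools["NAD_total"] - nadh,
            atp, pools["A_total"] - atp,
            ini["psi"],
        ])

    def fluxes(self, state: np.ndarray, k_load: float | None = None) -> dict:
        S, M1, M2, NADH, NAD, ATP, ADP, psi = state
        rx = self.config["reactions"]
        kl = rx["load"]["k_load"] if k_load is None else k_load
        v = {}
        v["supply"] = rx["supply"]["vmax"] / (1.0 + max(S, 0.0) / rx["supply"]["K_i"])
        v["tca_a"] = (
            rx["tca_a"]["vmax"]
            * S / (S + rx["tca_a"]["K_S"])
            * NAD / (NAD + rx["tca_a"]["K_NAD"])
        )
        v["tca_b"] = rx["tca_b"]["vmax"] * M1 / (M1 + rx["tca_b"]["K_M1"])
        v["tca_c"] = (
            rx["tca_c"]["vmax"]
            * M2 / (M2 + rx["tca_c"]["K_M2"])
            * NAD / (NAD + rx["tca_c"]["K_NAD"])
        )
        # respiratory lump: Michaelis-Menten in NADH, back-pressure from psi
        p = rx["etc"]
        v["etc"] = (
            p["vmax"] * NADH / (NADH + p["K_NADH"])
            / (1.0 + np.exp((psi - p["psi_max"]) / p["psi_slope"]))
        )
        p = rx["synthase"]
        v["synthase"] = (
            p["vmax"] * ADP / (ADP + p["K_ADP"])
            / (1.0 + np.exp((p["psi_half"] - psi) / p["psi_slope"]))
        )
        p = rx["leak"]
        v["leak"] = p["vmax"] * psi / (psi + p["K_psi"]) if psi > 0 else 0.0
        v["load"] = atp_load(ATP, kl, rx["load"]["K_m"])
        return v

    def rhs(self, t: float, state: np.ndarray, k_load: float | None = None) -> np.ndarray:
        v = self.fluxes(state, k_load)
        mem = self.config["membrane"]
        dS = v["supply"] - v["tca_a"]
        dM1 = v["tca_a"] - v["tca_b"]
        dM2 = v["tca_b"] - v["tca_c"]
        dNADH = v["tca_a"] + v["tca_c"] - v["etc"]
        dATP = v["synthase"] - v["load"]
        dpsi = (
            mem["n_pump"] * v["etc"]
            - mem["n_syn"] * v["synthase"]
            - v["leak"]
        ) / mem["c_mem"]
        return np.array([dS, dM1, dM2, dNADH, -dNADH, dATP, -dATP, dpsi])


@dataclass
class SteadyState:
    """Steady-state solution: state values, fluxes, convergence diagnostics."""

    state: pd.Series
    fluxes: pd.Series
    converged: bool
    residual: float
    trajectory: pd.DataFrame | None = None

    @property
    def atp(self) -> float:
        return float(self.state["ATP"])

    @property
    def atp_adp_ratio(self) -> float:
        return float(self.state["ATP"] / self.state["ADP"])


@dataclass
class LoadCurve:
    """Steady-state ATP metrics along a k_load titration."""

    table: pd.DataFrame  # columns: k_load, ATP, ATP_ADP, v_atp, converged
    max_atp_production: float
    k_load_at_max: float
    converged: bool


@dataclass
class RectificationResult:
    """Effect of resetting one protein group to control abundance."""

    group: str
    steady: SteadyState
    atp_gain: float            # ATP(rectified) - ATP(case)
    atp_vs_control: float      # ATP(rectified) - ATP(control)
    max_atp_production: float | None = None


def build_reference_model(config: Mapping | None = None) -> KineticModel:
    """Build the reference (healthy-control) model.

    ``config`` overrides the default parameterisation; it must supply every
    ``v_max``/``K_m``/pool it replaces — parameters are validated, never
    fitted.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if config:
        cfg = _deep_update(cfg, dict(config))
    protein_map = {k: list(v) for k, v in cfg.pop("protein_map").items()}
    required = {"pools", "initial", "membrane", "reactions"}
    missing = required - set(cfg)
    if missing:
        raise ValueError(f"config missing sections: {sorted(missing)}")
    return KineticModel(cfg, protein_map)


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            base[k] = _deep_update(base[k], dict(v))
        else:
            base[k] = v
    return base


def scale_vmax(
    model: KineticModel,
    profile: Mapping[str, float] | pd.Series,
    *,
    missing_policy: Literal["hold-at-1", "error"] = "hold-at-1",
    aggregate: Literal["mean", "geometric"] = "mean",
) -> KineticModel:
    """Scale each reaction's v_max by the relative abundance of its proteins.

    The factor for a multi-protein reaction is the arithmetic mean (or
    geometric mean) of the mapped proteins' relative abundances
    ``E(sample)/E(mean control)``.  Proteins absent from the profile are
    held at 1 or raise, per ``missing_policy``.
    """
    prof = pd.Series(profile, dtype=float)
    if (prof <= 0).any():
        raise ValueError("abundance factors must be > 0")
    scaled = model.copy()
    for rid, proteins in model.protein_map.items():
        factors = []
        for p in proteins:
            if p in prof.index:
                factors.append(float(prof[p]))
            elif missing_policy == "error":
                raise KeyError(f"protein {p!r} (reaction {rid!r}) absent from profile")
            else:
                factors.append(1.0)
        if aggregate == "mean":
            factor = float(np.mean(factors))
        else:
            factor = float(np.exp(np.mean(np.log(factors))))
        scaled.config["reactions"][rid]["vmax"] = (
            model.config["reactions"][rid]["vmax"] * factor
        )
    return scaled


def atp_load(atp: float, k_load: float, K_m: float) -> float:
    """Hyperbolic ATP consumption rate ``v = k_load * ATP/(ATP + K_m)``."""
    if k_load <= 0 or K_m <= 0:
        raise ValueError("k_load and K_m must be > 0")
    if atp <= 0:
        return 0.0
    return k_load * atp / (atp + K_m)


def steady_state(
    model: KineticModel,
    k_load: float | None = None,
    *,
    residual_tol: float = 1e-8,
    max_time: float = 2.0e5,
    chunk_time: float = 2000.0,
    keep_trajectory: bool = False,
) -> SteadyState:
    """Integrate the model to quiescence and report the steady state.

    Integration proceeds in chunks of ``chunk_time`` seconds with a stiff
    solver until the relative residual ``max_i |dx_i/dt| / scale_i`` drops
    below ``residual_tol`` or ``max_time`` is exhausted; non-convergence is
    flagged, not raised.
    """
    state = model.initial_state()
    scales = np.maximum(np.abs(state), 1e-3)
    scales[-1] = max(scales[-1], 1.0)  # psi in mV
    t = 0.0
    converged = False
    traj = [] if keep_trajectory else None
    while t < max_time:
        sol = solve_ivp(
            model.rhs,
            (t, t + chunk_time),
            state,
            args=(k_load,),
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
            dense_output=False,
        )
        if not sol.success:
            break
        state = sol.y[:, -1]
        if keep_trajectory:
            traj.append(pd.DataFrame(sol.y.T, index=sol.t, columns=STATE_NAMES))
        t = sol.t[-1]
        resid = np.max(np.abs(model.rhs(t, state, k_load)) / scales)
        if resid < residual_tol:
            converged = True
            break
    resid = float(np.max(np.abs(model.rhs(t, state, k_load)) / scales))
    fluxes = model.fluxes(state, k_load)
    return SteadyState(
        state=pd.Series(state, index=STATE_NAMES),
        fluxes=pd.Series(fluxes),
        converged=converged,
        residual=resid,
        trajectory=pd.concat(traj) if traj else None,
    )


def load_titration(
    model: KineticModel,
    *,
    k_load_start: float | None = None,
    step_factor: float = 1.25,
    max_steps: int = 30,
    convergence_threshold: float = 1e-3,
    residual_tol: float = 1e-8,
) -> LoadCurve:
    """Raise k_load in geometric steps until ATP production converges.

    At each step the steady state is recomputed; titration stops when the
    relative increase of the ATP consumption flux between consecutive
    steps falls below ``convergence_threshold`` (the flux has saturated at
    the model's maximal ATP production rate).
    """
    k0 = (
        model.config["reactions"]["load"]["k_load"]
        if k_load_start is None
        else k_load_start
    )
    rows = []
    prev_v = None
    converged = False
    k = k0
    for _ in range(max_steps):
        ss = steady_state(model, k_load=k, residual_tol=residual_tol)
        v_atp = float(ss.fluxes["load"])
        rows.append(
            {
                "k_load": k,
                "ATP": ss.atp,
                "ATP_ADP": ss.atp_adp_ratio,
                "v_atp": v_atp,
                "converged": ss.converged,
            }
        )
        if prev_v is not None and prev_v > 0:
            if (v_atp - prev_v) / prev_v < convergence_threshold:
                converged = True
                break
        prev_v = v_atp
        k *= step_factor
    if not converged:
        warnings.warn("load titration did not converge within the schedule")
    table = pd.DataFrame(rows)
    i_max = int(table["v_atp"].idxmax())
    return LoadCurve(
        table=table,
        max_atp_production=float(table["v_atp"].max()),
        k_load_at_max=float(table.loc[i_max, "k_load"]),
        converged=converged,
    )


def rectify(
    model_case: KineticModel,
    profile_case: Mapping[str, float] | pd.Series,
    groups: Mapping[str, Iterable[str]],
    *,
    reference_model: KineticModel | None = None,
    titrate: bool = False,
    residual_tol: float = 1e-8,
) -> dict[str, RectificationResult]:
    """In-silico rectification: reset protein groups to control abundance.

    For each named group, the case abundance profile is copied with that
    group's factors set to 1.0 (control level), the reference model is
    rescaled, and the steady state recomputed.  The result reports ATP
    gained over the un-rectified case and the remaining gap to the full
    control model.  ``titrate=True`` additionally reports the maximal ATP
    production rate of each rectified model.
    """
    prof = pd.Series(profile_case, dtype=float)
    mapped = model_case.mapped_proteins()
    for name, members in groups.items():
        members = set(members)
        if not members:
            raise ValueError(f"group {name!r} is empty")
        stray = members - mapped
        if stray:
            raise ValueError(f"group {name!r} has unmapped proteins: {sorted(stray)}")
    reference = reference_model if reference_model is not None else build_reference_model()
    ss_case = steady_state(model_case, residual_tol=residual_tol)
    ss_control = steady_state(reference, residual_tol=residual_tol)
    results: dict[str, RectificationResult] = {}
    for name, members in groups.items():
        rect_prof = prof.copy()
        for p in set(members) & set(rect_prof.index):
            rect_prof[p] = 1.0
        rect_model = scale_vmax(reference, rect_prof)
        ss = steady_state(rect_model, residual_tol=residual_tol)
        max_prod = (
            load_titration(rect_model, residual_tol=residual_tol).max_atp_production
            if titrate
            else None
        )
        results[name] = RectificationResult(
            group=name,
            steady=ss,
            atp_gain=ss.atp - ss_case.atp,
            atp_vs_control=ss.atp - ss_control.atp,
            max_atp_production=max_prod,
        )
    results["__case__"] = RectificationResult(
        group="__case__", steady=ss_case, atp_gain=0.0,
        atp_vs_control=ss_case.atp - ss_control.atp,
    )
    results["__control__"] = RectificationResult(
        group="__control__", steady=ss_control,
        atp_gain=ss_control.atp - ss_case.atp, atp_vs_control=0.0,
    )
    return results


def qc_scores(
    profile: Mapping[str, float] | pd.Series,
    model: KineticModel,
    *,
    cutoff: float = 75.0,
) -> dict:
    """Coverage scores for mapping a measured proteome onto the model.

    ``qc_score`` is the percentage of model-mapped proteins present in the
    abundance profile.  ``qsm_score`` is the percentage of scalable
    reactions whose protein requirement is covered; when a model declares
    redundant isoform groups for a reaction, each covered group counts, so
    the score can exceed 100%.  Both are reported against the standard 75%
    suitability cutoff.
    """
    prof_ids = set(pd.Series(profile, dtype=float).index)
    mapped = model.mapped_proteins()
    if not mapped:
        raise ValueError("model has no mapped proteins")
    qc = 100.0 * len(mapped & prof_ids) / len(mapped)
    n_reactions = len(model.protein_map)
    covered = 0.0
    for rid, proteins in model.protein_map.items():
        iso_groups = model.redundant_isoforms.get(rid) or [list(proteins)]
        covered += sum(1 for g in iso_groups if set(g) & prof_ids)
    qsm = 100.0 * covered / n_reactions
    return {
        "qc_score": qc,
        "qsm_score": qsm,
        "cutoff": cutoff,
        "passes_cutoff": bool(qc >= cutoff and qsm >= cutoff),
    }
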