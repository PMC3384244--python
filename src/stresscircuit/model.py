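"""Circuit definition: species, parameters, kinetic laws and the delayed RHS.

The model describes a self-limiting recombinant protein production circuit in
*E. coli*: IPTG induces T7 RNA polymerase, T7 polymerase drives GFP
transcription, and misfolded/aggregated GFP activates a stress promoter
(P_IbpAB-like) expressing a degradation-tagged TetR repressor that closes a
negative feedback loop onto the GFP gene. Folding intermediates partition
between the native (fluorescent) state and insoluble inclusion bodies.

Transcription and translation each carry an explicit time delay, so the
right-hand side consumes a *delayed-state lookup* in addition to the current
state; integration lives in :mod:`stresscircuit.dde`.

Units are arbitrary concentration units (nominally nM) and hours throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "SPECIES",
    "AUX_STATES",
    "N_SPECIES",
    "N_STATE",
    "CircuitParameters",
    "CircuitState",
    "FeedbackVariant",
    "InductionSchedule",
    "STANDARD_VARIANTS",
    "induction_factor",
    "repression_factor",
    "stress_activation",
    "rhs",
    "observables",
]

#: Dynamic species, in state-vector order.
SPECIES = ("m_T7", "p_T7", "m_G", "g_F", "g_N", "g_I", "m_R", "p_R")

#: Auxiliary cumulative-flux states appended to the vector; they let tests
#: close the GFP mass balance without re-integrating fluxes.
AUX_STATES = ("gfp_translated", "gfp_degraded", "gfp_diluted")

N_SPECIES = len(SPECIES)
N_STATE = N_SPECIES + len(AUX_STATES)


class CircuitError(ValueError):
    """Invalid parameter set, state or kinetic-function input."""


@dataclass(frozen=True)
class CircuitParameters:
    """Kinetic constants of the circuit.

    Defaults constitute the package's canonical calibrated fixture: an
    M9-glucose batch culture (mu0 ~ 0.6/h), a strong T7/GFP expression
    cassette whose load saturates the folding machinery, and a
    degradation-tagged TetR under a stress promoter.  All rates are per hour,
    concentrations in arbitrary units (nominally nM), IPTG in mM.

    Parameters
    ----------
    mu0
        Specific growth rate; dilutes every intracellular species.
    k_tx_T7, K_iptg, n_iptg, basal_T7
        T7-polymerase mRNA synthesis: maximal rate, IPTG half-activation
        constant (mM), Hill coefficient, and leaky basal fraction.
    k_tx_G, K_tetR, n_tetR
        GFP mRNA synthesis per active T7 polymerase and the TetR
        half-repression constant / Hill coefficient of the hybrid promoter.
    k_tx_R, basal_R, K_stress, n_stress
        Stress-promoter (TetR mRNA) kinetics: maximal rate, basal fraction,
        half-activation by the misfolded+aggregated GFP load, Hill
        coefficient.
    k_tl_T7, k_tl_G, k_tl_R
        Translation rates (proteins per mRNA per hour); ``k_tl_R`` encodes
        the RBS strength of the feedback cassette.
    tau_tx, tau_tl
        Transcription and translation delays (h), shared across genes.
    d_m, d_T7, d_G, d_R
        First-order degradation rates; ``d_R`` is large because TetR carries
        a degradation tag.
    k_fold, k_agg, K_fold_sat
        Folding-intermediate fate: folding rate to the native state,
        aggregation rate into inclusion bodies, and the half-saturation of
        the folding machinery (chaperone capacity).  ``K_fold_sat = inf``
        makes folding strictly first order.
    k_ib_deg
        Proteolytic clearance of inclusion-body protein.
    c_fluor
        Concentration of native GFP per normalized-fluorescence unit.
    """

    mu0: float = 0.6
    # IPTG -> T7 polymerase
    k_tx_T7: float = 40.0
    K_iptg: float = 0.05
    n_iptg: float = 2.0
    basal_T7: float = 0.02
    k_tl_T7: float = 12.0
    d_T7: float = 0.2
    # T7 -> GFP, repressed by TetR
    k_tx_G: float = 4.0
    K_tetR: float = 30.0
    n_tetR: float = 2.0
    k_tl_G: float = 40.0
    d_G: float = 0.05
    # stress -> TetR
    k_tx_R: float = 60.0
    basal_R: float = 0.05
    K_stress: float = 1200.0
    n_stress: float = 2.0
    k_tl_R: float = 10.0
    d_R: float = 2.0
    # shared mRNA turnover and delays
    d_m: float = 3.0
    tau_tx: float = 0.2
    tau_tl: float = 0.2
    # GFP folding / aggregation partition
    k_fold: float = 2.0
    k_agg: float = 2.0
    K_fold_sat: float = 1000.0
    k_ib_deg: float = 0.25
    # observation model
    c_fluor: float = 50.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) and not (f.name == "K_fold_sat" and v == math.inf):
                raise CircuitError(f"parameter {f.name} must be finite, got {v}")
            if v < 0:
                raise CircuitError(f"parameter {f.name} must be nonnegative, got {v}")
        for name in ("n_iptg", "n_tetR", "n_stress"):
            if getattr(self, name) < 1:
                raise CircuitError(f"Hill coefficient {name} must be >= 1")
        for name in ("basal_T7", "basal_R"):
            if not 0 <= getattr(self, name) <= 1:
                raise CircuitError(f"basal fraction {name} must lie in [0, 1]")

    def with_updates(self, **kwargs: float) -> "CircuitParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise CircuitError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def parameter_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class CircuitState:
    """Concentrations of every modeled species at one time point."""

    m_T7: float = 0.0
    p_T7: float = 0.0
    m_G: float = 0.0
    g_F: float = 0.0
    g_N: float = 0.0
    g_I: float = 0.0
    m_R: float = 0.0
    p_R: float = 0.0

    def __post_init__(self) -> None:
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise CircuitError(f"species {name} must be nonnegative")

    @property
    def total_gfp(self) -> float:
        return self.g_F + self.g_N + self.g_I

    @property
    def soluble_gfp(self) -> float:
        return self.g_F + self.g_N

    def to_vector(self) -> np.ndarray:
        """State vector including zeroed auxiliary cumulative fluxes."""
        y = np.zeros(N_STATE)
        for i, name in enumerate(SPECIES):
            y[i] = getattr(self, name)
        return y

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "CircuitState":
        vals = [max(float(v), 0.0) if v > -1e-9 else float(v) for v in y[:N_SPECIES]]
        return cls(*vals)


@dataclass(frozen=True)
class FeedbackVariant:
    """A promoter-strength x RBS-strength combination of the feedback cassette.

    ``promoter_scale`` multiplies both the maximal and basal stress-promoter
    activity (``k_tx_R``, ``basal_R``); ``rbs_scale`` multiplies the TetR
    translation rate ``k_tl_R``.  ``NO_FB`` removes the feedback entirely.
    """

    label: str
    promoter_scale: float = 1.0
    rbs_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.promoter_scale < 0 or self.rbs_scale < 0:
            raise CircuitError("variant scales must be nonnegative")
        if self.label == "NO_FB" and self.promoter_scale != 0:
            raise CircuitError("NO_FB variant must have promoter_scale = 0")

    def apply(self, params: CircuitParameters) -> CircuitParameters:
        """Return parameters with the variant's scales folded in."""
        return params.with_updates(
            k_tx_R=params.k_tx_R * self.promoter_scale,
            basal_R=min(params.basal_R * self.promoter_scale, 1.0),
            k_tl_R=params.k_tl_R * self.rbs_scale,
        )


#: The four expression setups characterized experimentally: no feedback,
#: wild-type stress promoter with strong RBS, promoter mutant with strong
#: RBS, and promoter mutant with weak RBS.  Scales are part of the canonical
#: calibrated fixture.
STANDARD_VARIANTS = {
    "NO_FB": FeedbackVariant("NO_FB", promoter_scale=0.0, rbs_scale=1.0),
    "WT_STRONG": FeedbackVariant("WT_STRONG", promoter_scale=1.0, rbs_scale=1.0),
    "MUT_STRONG": FeedbackVariant("MUT_STRONG", promoter_scale=0.5, rbs_scale=1.0),
    "MUT_WEAK": FeedbackVariant("MUT_WEAK", promoter_scale=0.5, rbs_scale=0.4),
}


@dataclass(frozen=True)
class InductionSchedule:
    """IPTG induction protocol for a batch culture."""

    iptg_conc: float = 1.0  # mM
    t_induce: float = 2.0  # h
    t_end: float = 12.0  # h

    def __post_init__(self) -> None:
        if self.iptg_conc < 0:
            raise CircuitError("iptg_conc must be nonnegative")
        if not 0 <= self.t_induce <= self.t_end:
            raise CircuitError("require 0 <= t_induce <= t_end")

    def iptg_at(self, t: float) -> float:
        """Medium IPTG concentration at time ``t`` (step at induction)."""
        return self.iptg_conc if t >= self.t_induce else 0.0


def induction_factor(iptg: float, params: CircuitParameters) -> float:
    """Fractional activity of the IPTG-inducible T7-polymerase promoter.

    Hill activation with a leaky basal floor:
    ``basal_T7 + (1 - basal_T7) * iptg^n / (K_iptg^n + iptg^n)``.
    Saturating IPTG (1 mM with K_iptg well below 1 mM) gives ~1.
    """
    if iptg < 0:
        raise CircuitError(f"IPTG concentration must be nonnegative, got {iptg}")
    if iptg == 0:
        return params.basal_T7
    h = iptg**params.n_iptg
    return params.basal_T7 + (1.0 - params.basal_T7) * h / (params.K_iptg**params.n_iptg + h)


def repression_factor(tetR: float, params: CircuitParameters) -> float:
    """Fractional promoter activity remaining under TetR repression.

    ``1 / (1 + (tetR/K_tetR)^n_tetR)``; strictly decreasing, ->0 as tetR->inf.
    """
    if tetR < 0:
        raise CircuitError(f"TetR concentration must be nonnegative, got {tetR}")
    if params.K_tetR == 0:
        return 0.0 if tetR > 0 else 1.0
    return 1.0 / (1.0 + (tetR / params.K_tetR) ** params.n_tetR)


def stress_load(y) -> float:
    """Misfolded + aggregated GFP load driving the stress promoter."""
    if isinstance(y, CircuitState):
        return y.g_F + y.g_I
    return float(y[3]) + float(y[5])


def stress_activation(state, params: CircuitParameters) -> float:
    """Fractional activity of the stress (P_IbpAB-like) promoter.

    The input signal is the unfolded + inclusion-body GFP load
    ``s = g_F + g_I`` (IbpA/B bind aggregated protein, so the sensor tracks
    the misfolded pool, not total product).  Basal activity persists with no
    stress.  Accepts a :class:`CircuitState` or a state vector.
    """
    s = stress_load(state)
    if s < 0:
        raise CircuitError("stress load must be nonnegative")
    if s == 0:
        return params.basal_R
    h = s**params.n_stress
    return params.basal_R + (1.0 - params.basal_R) * h / (params.K_stress**params.n_stress + h)


def _folding_flux(g_F: float, p: CircuitParameters) -> float:
    # saturable chaperone-assisted folding; first order when K_fold_sat = inf
    if math.isinf(p.K_fold_sat):
        return p.k_fold * g_F
    return p.k_fold * g_F / (1.0 + g_F / p.K_fold_sat)


def rhs(t, y, delayed, params: CircuitParameters, schedule: InductionSchedule):
    """Time derivative of the delayed circuit model.

    Parameters
    ----------
    t
        Current time, hours.
    y
        State vector (8 species + 3 cumulative GFP flux accumulators).
    delayed
        Callable ``delayed(t_query) -> state vector`` supplying the solution
        at ``t - tau_tx`` and ``t - tau_tl``; before time zero it must return
        the pre-induction history.
    params, schedule
        Kinetics and the induction protocol.

    Notes
    -----
    mRNA synthesis reads promoter/regulator states at ``t - tau_tx``;
    protein synthesis reads mRNA at ``t - tau_tl``.  Growth dilution ``mu0``
    drains every species.  The GFP folding intermediate pool g_F is drained
    by (saturable) folding into g_N, first-order aggregation into g_I and
    degradation/dilution; inclusion bodies g_I are cleared at ``k_ib_deg``
    plus dilution.
    """
    p = params
    mu = p.mu0
    y = np.asarray(y, dtype=float)
    # direct callers must supply physical states; the integrators clamp
    # solver trial values before calling (clip-or-reject lives there)
    neg_tol = 1e-9 * (1.0 + float(np.max(np.abs(y[:N_SPECIES]), initial=0.0)))
    if np.any(y[:N_SPECIES] < -neg_tol):
        bad = SPECIES[int(np.argmin(y[:N_SPECIES]))]
        raise CircuitError(f"negative species concentration for {bad} at t={t:.4f}")
    m_T7, p_T7, m_G, g_F, g_N, g_I, m_R, p_R = np.maximum(y[:N_SPECIES], 0.0)

    y_tx = np.maximum(np.asarray(delayed(t - p.tau_tx), dtype=float)[:N_SPECIES], 0.0)
    y_tl = np.maximum(np.asarray(delayed(t - p.tau_tl), dtype=float)[:N_SPECIES], 0.0)

    # transcription, from the regulator state one transcription delay ago
    act_T7 = induction_factor(schedule.iptg_at(t - p.tau_tx), p)
    prod_m_T7 = p.k_tx_T7 * act_T7
    prod_m_G = p.k_tx_G * y_tx[1] * repression_factor(y_tx[7], p)
    prod_m_R = p.k_tx_R * stress_activation(y_tx, p)

    # translation, from mRNA one translation delay ago
    prod_p_T7 = p.k_tl_T7 * y_tl[0]
    prod_g_F = p.k_tl_G * y_tl[2]
    prod_p_R = p.k_tl_R * y_tl[6]

    fold = _folding_flux(g_F, p)
    agg = p.k_agg * g_F

    d = np.empty(N_STATE)
    d[0] = prod_m_T7 - (p.d_m + mu) * m_T7
    d[1] = prod_p_T7 - (p.d_T7 + mu) * p_T7
    d[2] = prod_m_G - (p.d_m + mu) * m_G
    d[3] = prod_g_F - fold - agg - (p.d_G + mu) * g_F
    d[4] = fold - (p.d_G + mu) * g_N
    d[5] = agg - (p.k_ib_deg + mu) * g_I
    d[6] = prod_m_R - (p.d_m + mu) * m_R
    d[7] = prod_p_R - (p.d_R + mu) * p_R
    # cumulative GFP fluxes: translated in; degraded; diluted by growth
    d[8] = prod_g_F
    d[9] = p.d_G * (g_F + g_N) + p.k_ib_deg * g_I
    d[10] = mu * (g_F + g_N + g_I)
    return d


def observables(state, params: CircuitParameters) -> dict:
    """Derived read-outs for one state.

    ``soluble_fraction`` is (g_F + g_N) / total GFP, defined as 1.0 for an
    empty cell; ``fluorescence_equiv`` converts *native* GFP only — protein
    trapped in inclusion bodies is assumed non-fluorescent, which keeps the
    fluorescence calibration interpretable.
    """
    if not isinstance(state, CircuitState):
        state = CircuitState.from_vector(np.asarray(state, dtype=float))
    total = state.total_gfp
    soluble = state.soluble_gfp
    return {
        "total_gfp": total,
        "soluble_gfp": soluble,
        "soluble_fraction": soluble / total if total > 0 else 1.0,
        "fluorescence_equiv": state.g_N / params.c_fluor,
    }
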