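"""Per-agent metabolic response.

Local effective concentrations set Michaelis-Menten (or pool-drawdown)
upper bounds on uptake; a small stoichiometric model is then solved as a
linear program maximizing the biomass flux v_bio subject to steady-state
mass balance on internal metabolites, a non-growth ATP maintenance
requirement, and proportional-coupling constraints (e.g. methionine or
EPS secretion proportional to growth).  When even maintenance is
infeasible the cell shrinks at a fixed rate v_shrinkage.

An optional regression surrogate (a 2x15 multilayer perceptron by
default) can be fitted to LP evaluations to short-cut the flux
computation; scenarios run with the direct LP by default.

Sign convention for exchange fluxes: positive = secretion into the
medium, negative = uptake, in mmol g_DW^-1 h^-1 (g g_DW^-1 h^-1 for EPS).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "ToyStoichModel",
    "FluxResponse",
    "uptake_bound_active",
    "uptake_bound_passive",
    "solve_fluxes",
    "shrinkage_response",
    "Surrogate",
    "fit_surrogate",
    "surrogate_predict",
    "ModelDefinitionError",
]

#: default cell shrinkage rate under starvation, h^-1
V_SHRINKAGE = 1.6e-2

_BIG = 1e4  # default bound magnitude for unconstrained internal fluxes


class ModelDefinitionError(ValueError):
    pass


@dataclass(frozen=True)
class Reaction:
    id: str
    stoich: Mapping[str, float]
    lb: float = 0.0
    ub: float = _BIG


@dataclass
class ToyStoichModel:
    """A minimal stoichiometric flux model solved by LP.

    Parameters
    ----------
    name : str
    reactions : sequence of Reaction
        Stoichiometry over *internal* metabolites.  Exchange reactions
        additionally appear in ``exchanges`` mapping reaction id to the
        external metabolite they carry (positive flux = secretion).
    objective : str
        Id of the biomass reaction (flux unit h^-1).
    exchanges : dict
        reaction id -> external metabolite name.
    maintenance : (reaction id, flux) or None
        Fixed lower bound (mmol g_DW^-1 h^-1) on an ATP-drain reaction.
    couplings : dict
        reaction id -> ratio r, enforcing v_rxn = r * v_bio exactly.
    """

    name: str
    reactions: Sequence[Reaction]
    objective: str
    exchanges: dict[str, str] = field(default_factory=dict)
    maintenance: Optional[tuple[str, float]] = None
    couplings: dict[str, float] = field(default_factory=dict)
    v_shrinkage: float = V_SHRINKAGE

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ModelDefinitionError("duplicate reaction ids")
        if self.objective not in ids:
            raise ModelDefinitionError("objective must be a declared reaction")
        for rid in self.exchanges:
            if rid not in ids:
                raise ModelDefinitionError(f"unknown exchange reaction {rid}")
        for rid, ratio in self.couplings.items():
            if rid not in ids:
                raise ModelDefinitionError(f"unknown coupled reaction {rid}")
            if ratio < 0:
                raise ModelDefinitionError("coupling ratios must be >= 0")
        self._index = {rid: i for i, rid in enumerate(ids)}
        mets = sorted({m for r in self.reactions for m in r.stoich})
        self._mets = mets
        s = np.zeros((len(mets), len(ids)))
        mi = {m: i for i, m in enumerate(mets)}
        for j, r in enumerate(self.reactions):
            for m, c in r.stoich.items():
                s[mi[m], j] = c
        self._S = s
        self._lb = np.array([r.lb for r in self.reactions], dtype=float)
        self._ub = np.array([r.ub for r in self.reactions], dtype=float)
        if self.maintenance is not None:
            rid, flux = self.maintenance
            if rid not in self._index:
                raise ModelDefinitionError(f"unknown maintenance reaction {rid}")
            self._lb[self._index[rid]] = max(self._lb[self._index[rid]], flux)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def exchange_metabolites(self) -> list[str]:
        return list(self.exchanges.values())

    @property
    def uptake_metabolites(self) -> list[str]:
        """External metabolites this model can actually take up (their
        exchange reaction admits negative flux)."""
        return [
            met
            for rid, met in self.exchanges.items()
            if self._lb[self._index[rid]] < 0
        ]

    def reaction_index(self, rid: str) -> int:
        return self._index[rid]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "reactions": [
                    {"id": r.id, "stoich": dict(r.stoich), "lb": r.lb, "ub": r.ub}
                    for r in self.reactions
                ],
                "objective": self.objective,
                "exchanges": self.exchanges,
                "maintenance": list(self.maintenance) if self.maintenance else None,
                "couplings": self.couplings,
                "v_shrinkage": self.v_shrinkage,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ToyStoichModel":
        d = json.loads(text)
        return cls(
            name=d["name"],
            reactions=[Reaction(r["id"], r["stoich"], r["lb"], r["ub"]) for r in d["reactions"]],
            objective=d["objective"],
            exchanges=d.get("exchanges", {}),
            maintenance=tuple(d["maintenance"]) if d.get("maintenance") else None,
            couplings=d.get("couplings", {}),
            v_shrinkage=d.get("v_shrinkage", V_SHRINKAGE),
        )


@dataclass
class FluxResponse:
    """Outcome of one metabolic evaluation.

    ``v_bio`` in h^-1; ``exchange`` maps external metabolite name to its
    flux (positive = secretion, negative = uptake, mmol g_DW^-1 h^-1).
    ``feasible`` is False when no flux state satisfies maintenance, in
    which case the caller applies the shrinkage response.
    """

    v_bio: float
    exchange: dict[str, float]
    feasible: bool = True

    def uptake(self, met: str) -> float:
        """Magnitude of uptake of ``met`` (0 if secreted or absent)."""
        return max(0.0, -self.exchange.get(met, 0.0))

    def secretion(self, met: str) -> float:
        return max(0.0, self.exchange.get(met, 0.0))


def uptake_bound_active(v_max: float, k_m: float, c_eff) -> float:
    """Michaelis-Menten cap on active uptake: V_M * C / (K_M + C)."""
    if v_max < 0 or k_m <= 0:
        raise ValueError("V_M must be >= 0 and K_M > 0")
    c = np.asarray(c_eff, dtype=float)
    if np.any(c < 0):
        raise ValueError("effective concentration must be >= 0")
    out = v_max * c / (k_m + c)
    return float(out) if out.ndim == 0 else out


def uptake_bound_passive(v_max: float, rho_share: float, m_cell: float, dt: float) -> float:
    """Pool-drawdown cap on passive uptake: min(V_M, rho/(M dt)).

    The second argument of the min makes overdraw of the local pool
    impossible within one substep.
    """
    if min(v_max, rho_share) < 0 or dt <= 0:
        raise ValueError("inputs must be non-negative and dt > 0")
    if m_cell <= 0:
        raise ValueError("cell mass must be > 0")
    return min(v_max, rho_share / (m_cell * dt))


def solve_fluxes(
    model: ToyStoichModel,
    bounds: Mapping[str, float],
    tie_break: bool = True,
) -> FluxResponse:
    """Maximize v_bio by LP under mass balance, maintenance, couplings
    and per-metabolite uptake bounds.

    ``bounds`` maps external metabolite names to uptake caps v_U >= 0
    (the magnitude of the allowed uptake flux).  Metabolites absent from
    ``bounds`` keep the model's own exchange bounds.  Degenerate optima
    are resolved by a secondary LP minimizing the L1 norm of the
    exchange fluxes at fixed optimal v_bio, so secretion profiles are
    reproducible.
    """
    lb = model._lb.copy()
    ub = model._ub.copy()
    for rid, met in model.exchanges.items():
        if met in bounds:
            v_u = bounds[met]
            if not np.isfinite(v_u) or v_u < 0:
                raise ValueError(f"uptake bound for {met} must be finite and >= 0")
            j = model.reaction_index(rid)
            lb[j] = max(lb[j], -v_u)
    n = model.n_reactions
    a_eq = [model._S]
    b_eq = [np.zeros(model._S.shape[0])]
    j_bio = model.reaction_index(model.objective)
    for rid, ratio in model.couplings.items():
        row = np.zeros(n)
        row[model.reaction_index(rid)] = 1.0
        row[j_bio] = -ratio
        a_eq.append(row[None, :])
        b_eq.append([0.0])
    a_eq = np.vstack(a_eq)
    b_eq = np.concatenate([np.atleast_1d(b) for b in b_eq])
    c = np.zeros(n)
    c[j_bio] = -1.0
    res = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:  # infeasible: not even maintenance can be met
        return FluxResponse(v_bio=0.0, exchange={}, feasible=False)
    if res.status == 3:
        raise ModelDefinitionError(f"model {model.name}: LP is unbounded")
    if res.status != 0:
        raise ModelDefinitionError(f"model {model.name}: LP failed ({res.message})")
    v_opt = -res.fun
    v = res.x
    if tie_break and model.exchanges:
        v2 = _min_l1_exchange(model, lb, ub, a_eq, b_eq, j_bio, v_opt)
        if v2 is not None:
            v = v2
    exchange = {
        met: float(v[model.reaction_index(rid)]) for rid, met in model.exchanges.items()
    }
    # post-hoc contract check: no uptake bound violated
    for rid, met in model.exchanges.items():
        j = model.reaction_index(rid)
        if v[j] < lb[j] - 1e-7:
            raise ModelDefinitionError(
                f"model {model.name}: uptake bound violated for {met}"
            )
    return FluxResponse(v_bio=float(v[j_bio]), exchange=exchange, feasible=True)


def _min_l1_exchange(model, lb, ub, a_eq, b_eq, j_bio, v_opt):
    """Secondary LP: min sum |v_ex| subject to v_bio = v_opt."""
    n = model.n_reactions
    ex_idx = [model.reaction_index(rid) for rid in model.exchanges]
    m = len(ex_idx)
    # variables: v (n) then t (m) with t >= |v_ex|
    c = np.concatenate([np.zeros(n), np.ones(m)])
    a_eq2 = np.hstack([a_eq, np.zeros((a_eq.shape[0], m))])
    row = np.zeros(n + m)
    row[j_bio] = 1.0
    a_eq2 = np.vstack([a_eq2, row])
    b_eq2 = np.concatenate([b_eq, [v_opt]])
    a_ub = np.zeros((2 * m, n + m))
    for k, j in enumerate(ex_idx):
        a_ub[2 * k, j] = 1.0
        a_ub[2 * k, n + k] = -1.0
        a_ub[2 * k + 1, j] = -1.0
        a_ub[2 * k + 1, n + k] = -1.0
    b_ub = np.zeros(2 * m)
    var_bounds = list(zip(lb, ub)) + [(0, None)] * m
    res = linprog(
        c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq2, b_eq=b_eq2, bounds=var_bounds,
        method="highs",
    )
    if res.status != 0:
        return None
    return res.x[:n]


def shrinkage_response(model: ToyStoichModel) -> FluxResponse:
    """Starvation response: shrink at v_shrinkage with zero exchange.

    Called only when :func:`solve_fluxes` reports infeasibility; the
    negative v_bio feeds the same mass-update rule as growth, so the
    cell mass decays multiplicatively.
    """
    return FluxResponse(
        v_bio=-model.v_shrinkage,
        exchange={met: 0.0 for met in model.exchange_metabolites},
        feasible=False,
    )


# ---------------------------------------------------------------------------
# Regression surrogate for the LP response
# ---------------------------------------------------------------------------


@dataclass
class Surrogate:
    """A fitted regressor mapping uptake bounds to the flux response."""

    model: ToyStoichModel
    inputs: list[str]  # external metabolite order of the bound vector
    outputs: list[str]  # "v_bio" then exchange metabolite names
    regressor: object
    input_ranges: dict[str, tuple[float, float]]
    nmse: float
    pearson_r: float
    fallback: Callable[[Mapping[str, float]], FluxResponse] = None


def fit_surrogate(
    model: ToyStoichModel,
    input_ranges: Mapping[str, tuple[float, float]],
    n_samples: int = 5000,
    seed: int = 0,
    regressor=None,
) -> Surrogate:
    """Fit a surrogate to LP evaluations at sampled uptake bounds.

    Bounds are sampled uniformly over ``input_ranges`` (one range per
    external metabolite); 20% of the samples are held out to report the
    normalized mean squared error and Pearson r of the fit.
    """
    if n_samples < 100:
        raise ValueError("need at least 100 samples to fit a surrogate")
    rng = np.random.default_rng(seed)
    inputs = list(input_ranges)
    lo = np.array([input_ranges[m][0] for m in inputs])
    hi = np.array([input_ranges[m][1] for m in inputs])
    x = rng.uniform(lo, hi, size=(n_samples, len(inputs)))
    outputs = ["v_bio"] + model.exchange_metabolites
    y = np.empty((n_samples, len(outputs)))
    for i in range(n_samples):
        resp = solve_fluxes(model, dict(zip(inputs, x[i])))
        if not resp.feasible:
            resp = shrinkage_response(model)
        y[i] = [resp.v_bio] + [resp.exchange.get(m, 0.0) for m in outputs[1:]]
    n_test = max(1, n_samples // 5)
    perm = rng.permutation(n_samples)
    tr, te = perm[n_test:], perm[:n_test]
    if regressor is None:
        from sklearn.neural_network import MLPRegressor
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        regressor = make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=(15, 15),
                max_iter=4000,
                random_state=int(seed) % (2**31),
                tol=1e-7,
            ),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        regressor.fit(x[tr], y[tr])
    pred = np.atleast_2d(regressor.predict(x[te]))
    resid = pred - y[te]
    var = y[te].var()
    nmse = float((resid**2).mean() / var) if var > 0 else float((resid**2).mean())
    yf, pf = y[te].ravel(), pred.ravel()
    if yf.std() > 0 and pf.std() > 0:
        r = float(np.corrcoef(yf, pf)[0, 1])
    else:
        r = 1.0 if np.allclose(yf, pf) else 0.0
    return Surrogate(
        model=model,
        inputs=inputs,
        outputs=outputs,
        regressor=regressor,
        input_ranges=dict(input_ranges),
        nmse=nmse,
        pearson_r=r,
        fallback=lambda b: solve_fluxes(model, b),
    )


def surrogate_predict(surrogate: Surrogate, bounds: Mapping[str, float]) -> FluxResponse:
    """Predict the flux response from uptake bounds via the surrogate.

    Predictions are clipped so that no uptake exceeds its bound.  Bounds
    outside the fitted input ranges trigger a warning and fall back to
    the exact LP.
    """
    x = np.array([bounds.get(m, 0.0) for m in surrogate.inputs])
    for m, v in zip(surrogate.inputs, x):
        lo, hi = surrogate.input_ranges[m]
        if not lo <= v <= hi:
            warnings.warn(
                f"bound for {m} ({v:.3g}) outside surrogate range [{lo:.3g}, {hi:.3g}]; "
                "falling back to LP",
                stacklevel=2,
            )
            return surrogate.fallback(bounds)
    y = np.atleast_1d(np.asarray(surrogate.regressor.predict(x[None, :])).ravel())
    v_bio = float(y[0])
    exchange = {}
    for name, val in zip(surrogate.outputs[1:], y[1:]):
        if name in bounds:
            val = max(val, -bounds[name])  # clip uptake to its bound
        exchange[name] = float(val)
    return FluxResponse(v_bio=v_bio, exchange=exchange, feasible=True)
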