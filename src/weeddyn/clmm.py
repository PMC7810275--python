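"""Mixed cumulative-link (proportional-odds) transition model.

The probability that a field moves from coverage level *i* in year t-1 to
level *j* in year t is modelled through ordered logistic thresholds::

    P(Y_t <= j | Y_{t-1} = i, x, eps_s) = logistic(beta_{j|j+1} - eta),
    eta = alpha_i + beta' x + eps_s,

with strictly increasing thresholds beta_{0|1} < beta_{1|2} < beta_{2|3},
free previous-level effects alpha_i (alpha_0 = 0, treatment coding),
management covariates x (farmland use with baseline wheat, summer
irrigation, delayed sowing, Dec-Apr temperature in deg C, all treatment /
raw coded) and a site-level random intercept eps_s ~ Normal(0, sigma^2)
shared across all of a site's transitions.

Fitting maximizes the *marginal* likelihood: the random intercept is
integrated out per site, by adaptive Gauss-Hermite quadrature centred at
the per-site posterior mode (default, 15 nodes) or by the Laplace
approximation.  Threshold ordering is enforced throughout optimization via
a log-increment reparameterization; sigma is optimized on the log scale.

Model selection is greedy backward elimination on AIC = -2 loglik + 2 k,
where k counts the three thresholds, every included fixed-effect
coefficient, and sigma.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .survey import LAND_USES

logger = logging.getLogger("weeddyn.clmm")

__all__ = [
    "TERMS",
    "ModelSpec",
    "FittedModel",
    "FitOptions",
    "DesignData",
    "encode_design",
    "encode_profile_row",
    "conditional_transition_probs",
    "site_marginal_loglik",
    "marginal_loglik",
    "fit_model",
    "aic",
    "backward_select",
    "SelectionResult",
    "selection_table",
]

#: Closed set of model terms.
TERMS = ("prev_coverage", "irrigation", "delayed_sowing", "land_use", "temperature")

#: Non-baseline land-use dummy columns, in reporting order.
LAND_USE_DUMMIES = tuple(f"land_use[{u}]" for u in LAND_USES[1:])

#: Coefficient magnitude beyond which a category is flagged quasi-separated.
SEPARATION_THRESHOLD = 10.0

_COEF_BOUND = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed-effect terms enter the model, and how to integrate eps.

    The site random intercept is always present; ``quadrature`` selects the
    marginalization scheme ("gh" = adaptive Gauss-Hermite with ``n_nodes``
    nodes, "laplace" = Laplace approximation).
    """

    terms: frozenset[str] = frozenset(TERMS)
    quadrature: str = "gh"
    n_nodes: int = 15

    def __post_init__(self):
        unknown = set(self.terms) - set(TERMS)
        if unknown:
            raise ValueError(f"unknown model terms: {sorted(unknown)}")
        if self.quadrature not in ("gh", "laplace"):
            raise ValueError("quadrature must be 'gh' or 'laplace'")
        if self.quadrature == "gh" and (self.n_nodes < 1 or self.n_nodes % 2 == 0):
            raise ValueError("n_nodes must be odd and >= 1")
        object.__setattr__(self, "terms", frozenset(self.terms))

    def without(self, term: str) -> "ModelSpec":
        return replace(self, terms=self.terms - {term})

    @property
    def has_prev(self) -> bool:
        return "prev_coverage" in self.terms


def projection_spec(quadrature: str = "gh", n_nodes: int = 15) -> ModelSpec:
    """Spec with previous coverage, irrigation and farmland use only.

    This is the model used for all management projections: delayed sowing
    and temperature are excluded because their AIC contribution is below
    the ~2-unit noise floor and a projection model must not require a
    temperature scenario.
    """
    return ModelSpec(
        terms=frozenset({"prev_coverage", "irrigation", "land_use"}),
        quadrature=quadrature,
        n_nodes=n_nodes,
    )


# --------------------------------------------------------------------------
# design encoding
# --------------------------------------------------------------------------

@dataclass
class DesignData:
    """Transition pairs encoded for likelihood evaluation."""

    X: np.ndarray            # (n, k) fixed-effect design (excl. prev-level)
    names: list[str]         # k column names
    from_level: np.ndarray   # (n,) int previous-year level 0..3
    y: np.ndarray            # (n,) int observed level 0..3
    site_idx: np.ndarray     # (n,) int site code 0..S-1
    site_ids: list[str]
    spec: ModelSpec
    # warm start for the per-site posterior-mode search, updated in place
    # across likelihood evaluations (pure speed-up; values are re-solved
    # to tolerance on every call)
    eps_warm: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def site_starts(self) -> np.ndarray:
        # rows are sorted by site code; first row index of each site
        return np.searchsorted(self.site_idx, np.arange(self.n_sites))

    def __len__(self) -> int:
        return len(self.y)


def encode_design(pairs: pd.DataFrame, spec: ModelSpec) -> DesignData:
    """Encode a transition-pair table into design matrices.

    Treatment coding throughout: land-use baseline is wheat (all five
    dummies zero), previous-coverage baseline is level 0, temperature is
    passed raw in deg C.  Requesting the temperature term on pairs with
    missing temperature raises, naming the offending site-years.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if "irrigation" in spec.terms:
        cols.append(pairs["irrigation"].to_numpy(dtype=float))
        names.append("irrigation")
    if "delayed_sowing" in spec.terms:
        cols.append(pairs["delayed_sowing"].to_numpy(dtype=float))
        names.append("delayed_sowing")
    if "land_use" in spec.terms:
        lu = pairs["land_use"].astype(str)
        for use, name in zip(LAND_USES[1:], LAND_USE_DUMMIES):
            cols.append((lu == use).to_numpy(dtype=float))
            names.append(name)
    if "temperature" in spec.terms:
        t = pd.to_numeric(pairs["temp_dec_apr"], errors="coerce")
        if t.isna().any():
            bad = pairs.loc[t.isna(), ["site_id", "year"]]
            where = ", ".join(f"{r.site_id}/{r.year}" for r in bad.itertuples())
            raise ValueError(
                f"temperature term requested but temp_dec_apr missing for: {where}"
            )
        cols.append(t.to_numpy(dtype=float))
        names.append("temperature")

    X = np.column_stack(cols) if cols else np.empty((len(pairs), 0))
    site_ids = sorted(pairs["site_id"].astype(str).unique())
    code = {s: i for i, s in enumerate(site_ids)}
    site_idx = pairs["site_id"].astype(str).map(code).to_numpy(dtype=np.int64)
    order = np.argsort(site_idx, kind="stable")   # site-contiguous rows
    return DesignData(
        X=X[order],
        names=names,
        from_level=pairs["from_level"].to_numpy(dtype=np.int64)[order],
        y=pairs["to_level"].to_numpy(dtype=np.int64)[order],
        site_idx=site_idx[order],
        site_ids=site_ids,
        spec=spec,
    )


def encode_profile_row(profile: Mapping[str, object], spec: ModelSpec) -> dict[str, float]:
    """Encode a single covariate profile as a {coef name: value} row."""
    row: dict[str, float] = {}
    if "irrigation" in spec.terms:
        row["irrigation"] = float(profile.get("irrigation", 0))
    if "delayed_sowing" in spec.terms:
        row["delayed_sowing"] = float(profile.get("delayed_sowing", 0))
    if "land_use" in spec.terms:
        use = profile.get("land_use", "wheat")
        if use not in LAND_USES:
            raise ValueError(f"unknown land_use token {use!r}")
        for u, name in zip(LAND_USES[1:], LAND_USE_DUMMIES):
            row[name] = 1.0 if use == u else 0.0
    if "temperature" in spec.terms:
        t = profile.get("temp_dec_apr")
        if t is None or (isinstance(t, float) and math.isnan(t)):
            raise ValueError("temperature term requested but temp_dec_apr missing")
        row["temperature"] = float(t)
    return row


# --------------------------------------------------------------------------
# fitted model container
# --------------------------------------------------------------------------

@dataclass
class FittedModel:
    """Estimated thresholds, level effects, coefficients and random-effect SD."""

    spec: ModelSpec
    thresholds: np.ndarray          # (3,) strictly increasing, logit scale
    alpha: np.ndarray               # (3,) effects of prev level 1..3 (alpha_0 = 0)
    coefs: dict[str, float]         # named fixed-effect coefficients
    sigma: float                    # random-intercept SD (>= 0)
    loglik: float                   # marginal log-likelihood at the optimum
    n_params: int
    aic: float
    converged: bool
    grad_norm: float
    warnings: list[str] = field(default_factory=list)
    se: dict[str, float] | None = None
    n_pairs: int = 0
    n_sites: int = 0

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not (self.thresholds[0] < self.thresholds[1] < self.thresholds[2]):
            raise ValueError("thresholds must be strictly increasing")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    # -- linear predictor -------------------------------------------------
    def linear_predictor(self, from_level: int, x: Mapping[str, float],
                         epsilon: float = 0.0) -> float:
        if from_level not in (0, 1, 2, 3):
            raise ValueError("from_level must be in 0..3")
        eta = 0.0 if from_level == 0 else float(self.alpha[from_level - 1])
        if not self.spec.has_prev:
            eta = 0.0
        for name, beta in self.coefs.items():
            eta += beta * float(x.get(name, 0.0))
        return eta + epsilon

    # -- (de)serialization ------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "terms": sorted(self.spec.terms),
            "quadrature": self.spec.quadrature,
            "n_nodes": self.spec.n_nodes,
            "thresholds": [float(v) for v in self.thresholds],
            "alpha": [float(v) for v in self.alpha],
            "coefs": {k: float(v) for k, v in self.coefs.items()},
            "sigma": float(self.sigma),
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "grad_norm": float(self.grad_norm),
            "warnings": list(self.warnings),
            "se": None if self.se is None else {k: float(v) for k, v in self.se.items()},
            "n_pairs": int(self.n_pairs),
            "n_sites": int(self.n_sites),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        spec = ModelSpec(terms=frozenset(doc["terms"]), quadrature=doc["quadrature"],
                         n_nodes=doc["n_nodes"])
        return cls(
            spec=spec,
            thresholds=np.array(doc["thresholds"]),
            alpha=np.array(doc["alpha"]),
            coefs=dict(doc["coefs"]),
            sigma=doc["sigma"],
            loglik=doc["loglik"],
            n_params=doc["n_params"],
            aic=doc["aic"],
            converged=doc["converged"],
            grad_norm=doc["grad_norm"],
            warnings=list(doc["warnings"]),
            se=doc.get("se"),
            n_pairs=doc.get("n_pairs", 0),
            n_sites=doc.get("n_sites", 0),
        )


def make_true_model(thresholds: Sequence[float], alpha: Sequence[float],
                    coefs: Mapping[str, float], sigma: float,
                    spec: ModelSpec | None = None) -> FittedModel:
    """Assemble a FittedModel-shaped parameter set (for simulation truths)."""
    if spec is None:
        terms = {"prev_coverage"} if any(alpha) else set()
        if "irrigation" in coefs:
            terms.add("irrigation")
        if "delayed_sowing" in coefs:
            terms.add("delayed_sowing")
        if any(n in LAND_USE_DUMMIES for n in coefs):
            terms.add("land_use")
        if "temperature" in coefs:
            terms.add("temperature")
        spec = ModelSpec(terms=frozenset(terms))
    k = len(coefs) + (3 if spec.has_prev else 0)
    return FittedModel(
        spec=spec,
        thresholds=np.asarray(thresholds, dtype=float),
        alpha=np.asarray(alpha, dtype=float),
        coefs=dict(coefs),
        sigma=float(sigma),
        loglik=float("nan"),
        n_params=3 + k + 1,
        aic=float("nan"),
        converged=True,
        grad_norm=0.0,
    )


# --------------------------------------------------------------------------
# conditional transition probabilities
# --------------------------------------------------------------------------

def _interval_probs(c: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """P(Y = j) for j = 0..3 given thresholds c (3,) and predictor eta (...).

    Returns an array of shape eta.shape + (4,); rows sum to 1 and saturate
    cleanly for eta -> +-inf.
    """
    eta = np.asarray(eta, dtype=float)
    cum = expit(c - eta[..., None])         # (..., 3) cumulative P(Y<=j)
    p = np.empty(eta.shape + (4,))
    p[..., 0] = cum[..., 0]
    p[..., 1] = cum[..., 1] - cum[..., 0]
    p[..., 2] = cum[..., 2] - cum[..., 1]
    p[..., 3] = 1.0 - cum[..., 2]
    return np.clip(p, 0.0, 1.0)


def conditional_transition_probs(model: FittedModel, from_level: int,
                                 x: Mapping[str, float] | None = None,
                                 epsilon: float = 0.0) -> np.ndarray:
    """The 4-vector (p_0i, p_1i, p_2i, p_3i) for previous level i.

    ``x`` maps coefficient names (as in ``model.coefs``) to values; omitted
    names count as zero (the wheat / no-management baseline).
    """
    eta = model.linear_predictor(from_level, x or {}, epsilon)
    if np.isinf(eta):
        p = np.zeros(4)
        p[0 if eta < 0 else 3] = 1.0
        return p
    p = _interval_probs(model.thresholds, np.array(eta))
    return p / p.sum()


# --------------------------------------------------------------------------
# marginal likelihood machinery
# --------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=8)
def _hermgauss(n: int):
    return np.polynomial.hermite.hermgauss(n)


def _category_bounds(c: np.ndarray, y: np.ndarray):
    """Interval bounds (c_{y-1}, c_y) per observation, +-inf at the ends."""
    cpad = np.concatenate(([-np.inf], c, [np.inf]))
    return cpad[y], cpad[y + 1]


def _log_category_probs(c: np.ndarray, eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """log P(Y = y) for each observation; stable under saturation."""
    lo, hi = _category_bounds(c, y)
    p = expit(hi - eta) - expit(lo - eta)
    return np.log(np.maximum(p, 1e-320))


def _dlog_terms(c: np.ndarray, eta: np.ndarray, y: np.ndarray):
    """First and second derivatives of log P(Y=y) with respect to eta."""
    # interval bounds a = c_{y-1} - eta, b = c_y - eta (a = -inf / b = +inf at ends)
    cpad = np.concatenate(([-np.inf], c, [np.inf]))
    a = cpad[y] - eta
    b = cpad[y + 1] - eta
    Fa, Fb = expit(a), expit(b)
    fa = np.where(np.isfinite(a), Fa * (1.0 - Fa), 0.0)
    fb = np.where(np.isfinite(b), Fb * (1.0 - Fb), 0.0)
    dfa = np.where(np.isfinite(a), fa * (1.0 - 2.0 * Fa), 0.0)
    dfb = np.where(np.isfinite(b), fb * (1.0 - 2.0 * Fb), 0.0)
    p = np.maximum(Fb - Fa, 1e-320)
    # d/deta log p: interval shifts with -eta, so signs flip once
    g = (fa - fb) / p
    h = (dfb - dfa) / p - g * g
    return g, h


def _site_modes(c, alpha_eta, sigma, data: DesignData, eps0: np.ndarray | None = None):
    """Posterior mode and curvature of eps per site, by safeguarded Newton.

    The per-site objective h(eps) = sum log p(eta + eps) - eps^2 / (2 sigma^2)
    is strictly concave (logistic interval log-probabilities are concave in
    the location), so Newton with step halving converges.
    """
    S = data.n_sites
    eps = np.zeros(S) if eps0 is None else eps0.copy()
    idx = data.site_idx

    def value(e):
        lp = _log_category_probs(c, alpha_eta + e[idx], data.y)
        return np.bincount(idx, weights=lp, minlength=S) - 0.5 * e * e / sigma**2

    val = value(eps)
    for _ in range(50):
        g_i, h_i = _dlog_terms(c, alpha_eta + eps[idx], data.y)
        grad = np.bincount(idx, weights=g_i, minlength=S) - eps / sigma**2
        curv = np.bincount(idx, weights=h_i, minlength=S) - 1.0 / sigma**2
        if np.max(np.abs(grad)) < 1e-9:
            break
        step = np.clip(-grad / curv, -5.0, 5.0)
        # damped step: halve per site while the site objective decreases
        new = eps + step
        newval = value(new)
        for _ in range(10):
            worse = newval < val - 1e-10
            if not worse.any():
                break
            step = np.where(worse, 0.5 * step, step)
            new = eps + step
            newval = value(new)
        eps, val = new, newval
        if np.max(np.abs(step)) < 1e-10:
            break
    g_i, h_i = _dlog_terms(c, alpha_eta + eps[idx], data.y)
    curv = np.bincount(idx, weights=h_i, minlength=S) - 1.0 / sigma**2
    return eps, curv


def _marginal_loglik_parts(c, alpha, beta, sigma, data: DesignData,
                           quadrature: str, n_nodes: int) -> np.ndarray:
    """Per-site marginal log-likelihood contributions."""
    eta_fix = data.X @ beta if data.X.size else np.zeros(len(data))
    if data.spec.has_prev:
        a_full = np.concatenate(([0.0], alpha))
        eta_fix = eta_fix + a_full[data.from_level]
    S = data.n_sites
    if sigma < 1e-10:
        lp = _log_category_probs(c, eta_fix, data.y)
        return np.bincount(data.site_idx, weights=lp, minlength=S)

    eps_hat, curv = _site_modes(c, eta_fix, sigma, data, eps0=data.eps_warm)
    data.eps_warm = eps_hat
    tau = 1.0 / np.sqrt(-curv)          # curvature is strictly negative
    log_prior_norm = -0.5 * math.log(2.0 * math.pi) - math.log(sigma)

    def h_of(e_sites):
        lp = _log_category_probs(c, eta_fix + e_sites[data.site_idx], data.y)
        site_lp = np.bincount(data.site_idx, weights=lp, minlength=S)
        return site_lp - 0.5 * e_sites**2 / sigma**2

    if quadrature == "laplace":
        h_hat = h_of(eps_hat)
        return log_prior_norm + h_hat + 0.5 * math.log(2.0 * math.pi) + np.log(tau)

    # integral e^{h} deps ~ sqrt(2) tau sum_m w_m exp(x_m^2) e^{h(eps_hat + sqrt2 tau x_m)}
    nodes, weights = _hermgauss(n_nodes)
    eps_mat = eps_hat[:, None] + math.sqrt(2.0) * tau[:, None] * nodes[None, :]
    lo, hi = _category_bounds(c, data.y)
    eta_all = eta_fix[:, None] + eps_mat[data.site_idx]            # (n, M)
    p = expit(hi[:, None] - eta_all) - expit(lo[:, None] - eta_all)
    lp = np.log(np.maximum(p, 1e-320))
    site_lp = np.add.reduceat(lp, data.site_starts, axis=0)        # (S, M)
    H = (site_lp - 0.5 * eps_mat**2 / sigma**2
         + nodes[None, :] ** 2 + np.log(weights)[None, :])
    return log_prior_norm + 0.5 * math.log(2.0) + np.log(tau) + logsumexp(H, axis=1)


def marginal_loglik(c, alpha, beta, sigma, data: DesignData,
                    quadrature: str = "gh", n_nodes: int = 15) -> float:
    """Total marginal log-likelihood over all sites."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return float(_marginal_loglik_parts(np.asarray(c, float),
                                        np.asarray(alpha, float),
                                        np.asarray(beta, float),
                                        float(sigma), data, quadrature, n_nodes).sum())


def site_marginal_loglik(model: FittedModel, site_pairs: pd.DataFrame,
                         spec: ModelSpec | None = None,
                         quadrature: str | None = None,
                         n_nodes: int | None = None) -> float:
    """Marginal log-likelihood of one site's transition pairs.

    Integrates the shared site intercept out of the product of multinomial
    transition probabilities:  log int prod_k p_{y_k}(x_k, eps)
    phi(eps; 0, sigma^2) d eps.
    """
    if site_pairs.empty:
        raise ValueError("site_pairs must be non-empty")
    if site_pairs["site_id"].nunique() != 1:
        raise ValueError("site_pairs must come from a single site")
    spec = spec or model.spec
    data = encode_design(site_pairs, spec)
    beta = np.array([model.coefs.get(n, 0.0) for n in data.names])
    return marginal_loglik(
        model.thresholds, model.alpha, beta, model.sigma, data,
        quadrature or spec.quadrature, n_nodes or spec.n_nodes,
    )


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit_model`."""

    n_starts: int = 3          # null start, jittered start, sigma~0 warm start
    maxiter: int = 600
    gtol: float = 1e-6
    seed: int = 0
    compute_se: bool = False
    fix_sigma: float | None = None   # fit with sigma pinned (0 = fixed effects)


def _unpack(theta: np.ndarray, k: int, has_prev: bool, fix_sigma: float | None):
    c1, d1, d2 = theta[0], theta[1], theta[2]
    c = np.array([c1, c1 + np.exp(d1), c1 + np.exp(d1) + np.exp(d2)])
    pos = 3
    if has_prev:
        alpha = theta[pos:pos + 3]
        pos += 3
    else:
        alpha = np.zeros(3)
    beta = theta[pos:pos + k]
    pos += k
    sigma = fix_sigma if fix_sigma is not None else float(np.exp(theta[pos]))
    return c, alpha, beta, sigma


def _pack(c, alpha, beta, sigma, has_prev: bool, fix_sigma: float | None):
    d1 = np.log(max(c[1] - c[0], 1e-8))
    d2 = np.log(max(c[2] - c[1], 1e-8))
    parts = [np.array([c[0], d1, d2])]
    if has_prev:
        parts.append(np.asarray(alpha, float))
    parts.append(np.asarray(beta, float))
    if fix_sigma is None:
        parts.append(np.array([np.log(max(sigma, 1e-6))]))
    return np.concatenate(parts)


def fit_model(pairs: pd.DataFrame, spec: ModelSpec,
              options: FitOptions | None = None) -> FittedModel:
    """Fit the mixed cumulative-link transition model by marginal ML.

    Multi-start quasi-Newton (L-BFGS-B) on the reparameterized objective;
    threshold ordering holds at every iterate by construction.  Returns a
    :class:`FittedModel` with a convergence flag and the projected-gradient
    norm; non-convergence never raises, it is reported in the result.
    """
    opts = options or FitOptions()
    data = encode_design(pairs, spec)
    k = len(data.names)
    has_prev = spec.has_prev
    fix = opts.fix_sigma

    def negll(theta):
        c, alpha, beta, sigma = _unpack(theta, k, has_prev, fix)
        return -marginal_loglik(c, alpha, beta, sigma, data,
                                spec.quadrature, spec.n_nodes)

    nb = k + (3 if has_prev else 0)
    bounds = ([(-_COEF_BOUND, _COEF_BOUND), (-10.0, 5.0), (-10.0, 5.0)]
              + [(-_COEF_BOUND, _COEF_BOUND)] * nb
              + ([] if fix is not None else [(-8.0, 3.0)]))

    rng = np.random.default_rng(opts.seed)
    null_start = _pack(np.array([-1.0, 0.0, 1.0]), np.zeros(3), np.zeros(k),
                       0.6, has_prev, fix)
    starts = [null_start]
    if opts.n_starts >= 2:
        starts.append(null_start + rng.normal(0.0, 0.5, size=null_start.size))
    if opts.n_starts >= 3 and fix is None:
        # warm start: conditional (sigma ~ 0) fit, then free the variance
        warm = minimize(
            lambda th: -marginal_loglik(*_unpack(th, k, has_prev, 0.0)[:3], 0.0,
                                        data, spec.quadrature, spec.n_nodes),
            _pack(np.array([-1.0, 0.0, 1.0]), np.zeros(3), np.zeros(k), 0.0,
                  has_prev, 0.0),
            method="L-BFGS-B", jac="3-point", bounds=bounds[:3 + nb],
            options={"maxiter": opts.maxiter, "ftol": 1e-12, "gtol": opts.gtol},
        )
        starts.append(np.concatenate([warm.x, [np.log(0.6)]]))

    best = None
    for start_no, x0 in enumerate(starts[: max(opts.n_starts, 1)]):
        res = minimize(negll, x0, method="L-BFGS-B", jac="3-point", bounds=bounds,
                       options={"maxiter": opts.maxiter, "ftol": 1e-12,
                                "gtol": opts.gtol})
        logger.debug("fit start=%d nit=%d loglik=%.6f success=%s",
                     start_no, res.nit, -res.fun, res.success)
        if best is None or res.fun < best.fun:
            best = res

    c, alpha, beta, sigma = _unpack(best.x, k, has_prev, fix)
    loglik = -best.fun
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.inf
    n_params = 3 + (3 if has_prev else 0) + k + 1
    model_aic = -2.0 * loglik + 2.0 * n_params

    warnings: list[str] = []
    coefs = dict(zip(data.names, (float(b) for b in beta)))
    for name, val in coefs.items():
        if abs(val) > SEPARATION_THRESHOLD:
            warnings.append(f"quasi-separation: |{name}| = {abs(val):.2f} > 10")
    if has_prev:
        a = alpha
        mono = (0 < a[0] < a[1] < a[2]) or (a[2] < a[1] < a[0] < 0)
        if not mono:
            warnings.append("previous-level effects alpha are not monotone")
    if not best.success:
        warnings.append(f"optimizer: {best.message}")

    for w in warnings:
        logger.warning("fit terms=%s: %s", sorted(spec.terms), w)
    logger.info("fit terms=%s loglik=%.4f aic=%.2f converged=%s grad_norm=%.2e",
                sorted(spec.terms), loglik, model_aic, best.success, grad_norm)

    se = None
    if opts.compute_se:
        se = _wald_se(best.x, negll, data.names, has_prev, fix)

    return FittedModel(
        spec=spec, thresholds=c, alpha=np.asarray(alpha, float), coefs=coefs,
        sigma=float(sigma), loglik=float(loglik), n_params=n_params,
        aic=float(model_aic), converged=bool(best.success),
        grad_norm=grad_norm, warnings=warnings, se=se,
        n_pairs=len(data), n_sites=data.n_sites,
    )


def _wald_se(theta_hat: np.ndarray, negll, names: list[str],
             has_prev: bool, fix_sigma: float | None) -> dict[str, float]:
    """Wald standard errors from the numerically differenced observed information.

    SEs for the raw optimizer coordinates; coefficient coordinates are their
    own natural scale, so e.g. the irrigation SE is directly usable.
    """
    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(theta_hat, negll)
    labels = ["threshold_0|1", "log_incr_1", "log_incr_2"]
    if has_prev:
        labels += ["prev_lv1", "prev_lv2", "prev_lv3"]
    labels += list(names)
    if fix_sigma is None:
        labels += ["log_sigma"]
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        se = np.sqrt(np.where(diag > 0, diag, np.nan))
    except np.linalg.LinAlgError:
        se = np.full(len(labels), np.nan)
    return dict(zip(labels, (float(s) for s in se)))


def aic(fit: FittedModel) -> float:
    """AIC = -2 loglik + 2 n_params."""
    if not np.isfinite(fit.loglik):
        raise ValueError("loglik must be finite")
    return -2.0 * fit.loglik + 2.0 * fit.n_params


# --------------------------------------------------------------------------
# backward selection
# --------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Greedy AIC elimination trace: every evaluated candidate plus the winner."""

    ladder: list[tuple[ModelSpec, FittedModel]]
    best_spec: ModelSpec
    best: FittedModel
    failed: list[tuple[ModelSpec, str]] = field(default_factory=list)


_AIC_TIE = 1e-6


def backward_select(pairs: pd.DataFrame, full_spec: ModelSpec,
                    options: FitOptions | None = None) -> SelectionResult:
    """Backward elimination on AIC starting from ``full_spec``.

    At each stage the single term whose removal lowers AIC the most is
    dropped; elimination stops when no removal lowers AIC.  Ties within
    1e-6 resolve toward the smaller model.  Every evaluated candidate is
    kept in the ladder; candidates that fail to converge are excluded from
    the comparison with a warning.
    """
    opts = options or FitOptions()
    cache: dict[frozenset, FittedModel] = {}
    ladder: list[tuple[ModelSpec, FittedModel]] = []
    failed: list[tuple[ModelSpec, str]] = []

    def fitted(spec: ModelSpec) -> FittedModel:
        key = spec.terms
        if key not in cache:
            fit = fit_model(pairs, spec, opts)
            cache[key] = fit
            ladder.append((spec, fit))
        return cache[key]

    current_spec = full_spec
    current = fitted(full_spec)
    if not current.converged:
        failed.append((full_spec, "full model did not converge"))
    while current_spec.terms:
        candidates: list[tuple[float, ModelSpec, FittedModel]] = []
        for term in sorted(current_spec.terms):
            cand_spec = current_spec.without(term)
            fit = fitted(cand_spec)
            if not fit.converged:
                failed.append((cand_spec, "candidate did not converge"))
                continue
            candidates.append((fit.aic, cand_spec, fit))
        if not candidates:
            break
        # smallest AIC; on near-ties prefer fewer parameters (they sort later,
        # so compare with the tie tolerance explicitly)
        candidates.sort(key=lambda t: (t[0], len(t[1].terms)))
        best_aic, best_spec_c, best_fit = candidates[0]
        if best_aic <= current.aic + _AIC_TIE:
            current_spec, current = best_spec_c, best_fit
        else:
            break
    return SelectionResult(ladder=ladder, best_spec=current_spec, best=current,
                           failed=failed)


_TABLE_COLUMNS = (
    ["prev_lv1", "prev_lv2", "prev_lv3", "irrigation", "delayed_sowing"]
    + list(LAND_USE_DUMMIES)
    + ["temperature", "threshold_0|1", "threshold_1|2", "threshold_2|3", "aic"]
)


def selection_table(result: SelectionResult) -> pd.DataFrame:
    """Selection ladder as a coefficient table, one candidate per row.

    Excluded terms are blank (NaN); rows are sorted by AIC, mirroring the
    conventional presentation of backward-elimination results.
    """
    rows = []
    for spec, fit in result.ladder:
        row: dict[str, float] = {c: np.nan for c in _TABLE_COLUMNS}
        if spec.has_prev:
            row["prev_lv1"], row["prev_lv2"], row["prev_lv3"] = fit.alpha
        for name, val in fit.coefs.items():
            row[name] = val
        row["threshold_0|1"], row["threshold_1|2"], row["threshold_2|3"] = fit.thresholds
        row["aic"] = fit.aic
        rows.append(row)
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS).sort_values(
        "aic").reset_index(drop=True)
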