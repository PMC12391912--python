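"""Component-wise functional gradient boosting for distributional regression.

Every distribution parameter of the response family (location ``mu``, scale
``sigma`` and, for the zero-adjusted gamma, the zero-probability ``nu``) gets
its own additive predictor on the link scale, initialized at the unconditional
maximum-likelihood offset.  Candidate base learners are penalized least-squares
smoothers: P-splines for metric predictors (cubic B-spline basis, 20 interior
knots, second-order difference penalty, effective degrees of freedom fixed per
learner), simple linear learners for binary predictors, and intercept
learners.  "Variable coefficients" are separate base learners per grouping
cell (e.g. land use x census year), each fitting only the rows of its cell.

Per boosting iteration the gradient of the log-likelihood with respect to each
linked predictor is computed, every candidate learner is fit to its
parameter's gradient, and only the single (parameter, learner) pair whose
step-size-damped update most reduces the empirical negative log-likelihood is
added (non-cyclical update).  Early stopping via subsampled cross-validation
(``cv_tune``) provides the regularization: coefficients are shrunk toward zero
exactly as in L2-boosting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from savannagrad.families import Family, family_from_name

__all__ = [
    "BaseLearnerSpec",
    "BoostModel",
    "CVResult",
    "build_base_learners",
    "boost_fit",
    "cv_tune",
    "predict",
]

log = logging.getLogger(__name__)

P_SPLINE_KNOTS = 20
P_SPLINE_DEGREE = 3
P_SPLINE_PENALTY_ORDER = 2
DEFAULT_DF = 4.0


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One candidate learner: a predictor, a target parameter, a form, a cell."""

    param: str
    kind: str  # "intercept" | "linear" | "pspline"
    predictor: str = None
    cell: tuple = ()  # ((column, value), ...) -- empty for ungrouped learners

    @property
    def name(self):
        base = self.predictor or "(intercept)"
        cell = ",".join(f"{c}={v}" for c, v in self.cell) if self.cell else "all"
        return f"{self.param}~{base}[{cell}]"


def _difference_penalty(k, order):
    d = np.eye(k)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return d.T @ d


def _df_lambda(xtx, pen, target_df):
    """Penalty weight such that trace of the hat matrix equals target_df."""
    k = xtx.shape[0]
    ridge = 1e-10 * np.trace(xtx) / k

    def df_of(lam):
        m = xtx + lam * pen + ridge * np.eye(k)
        return float(np.trace(np.linalg.solve(m, xtx)))

    if df_of(0.0) <= target_df:
        return 0.0
    lo, hi = 1e-10, 1e-2
    while df_of(hi) > target_df and hi < 1e14:
        hi *= 10.0
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if df_of(mid) > target_df:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


class _FittedLearner:
    """A spec bound to training data: design matrix and pre-factored solver."""

    def __init__(self, spec, data, df_target=DEFAULT_DF):
        self.spec = spec
        self.rows = _cell_mask(data, spec.cell)
        self.n_rows = int(self.rows.sum())
        x = None
        if spec.predictor is not None:
            x = data.loc[self.rows, spec.predictor].to_numpy(dtype=float)
            if np.isnan(x).any():
                fill = np.nanmean(x)
                log.warning("predictor %s: %d missing values mean-filled",
                            spec.predictor, int(np.isnan(x).sum()))
                x = np.where(np.isnan(x), fill, x)
        self.params = {}
        if spec.kind == "intercept":
            design = np.ones((self.n_rows, 1))
            pen = np.zeros((1, 1))
        elif spec.kind == "linear":
            center, scale = float(np.mean(x)), float(np.std(x))
            if scale <= 0:
                raise ValueError(f"constant predictor in cell: {spec.name}")
            self.params = {"center": center, "scale": scale}
            design = np.column_stack([np.ones_like(x), (x - center) / scale])
            pen = np.zeros((2, 2))
        elif spec.kind == "pspline":
            lo, hi = float(np.min(x)), float(np.max(x))
            if hi <= lo:
                raise ValueError(f"constant predictor in cell: {spec.name}")
            pad = 1e-6 * (hi - lo)
            knots = np.linspace(lo - pad, hi + pad, P_SPLINE_KNOTS + 2)
            t = np.concatenate(
                [np.repeat(knots[0], P_SPLINE_DEGREE), knots, np.repeat(knots[-1], P_SPLINE_DEGREE)]
            )
            self.params = {"knots": t, "lo": lo, "hi": hi}
            design = BSpline.design_matrix(
                np.clip(x, lo, hi), t, P_SPLINE_DEGREE
            ).toarray()
            pen = _difference_penalty(design.shape[1], P_SPLINE_PENALTY_ORDER)
        else:  # pragma: no cover
            raise ValueError(f"unknown learner kind {spec.kind!r}")

        xtx = design.T @ design
        lam = _df_lambda(xtx, pen, df_target) if spec.kind == "pspline" else 0.0
        k = design.shape[1]
        ridge = 1e-9 * max(np.trace(xtx) / k, 1e-12)
        m = xtx + lam * pen + ridge * np.eye(k)
        self.design = design
        self.solver = np.linalg.solve(m, design.T)  # k x n_rows
        self.lam = lam
        self.coef = np.zeros(k)

    # -- fitting ----------------------------------------------------------
    def solve(self, u_full):
        """Penalized LS fit of this learner to the gradient vector."""
        u = u_full[self.rows]
        coef = self.solver @ u
        fitted = self.design @ coef
        return coef, fitted

    def design_for(self, data):
        """Design matrix and row mask of this learner on new data."""
        rows = _cell_mask(data, self.spec.cell)
        if self.spec.kind == "intercept":
            return np.ones((int(rows.sum()), 1)), rows
        x = data.loc[rows, self.spec.predictor].to_numpy(dtype=float)
        if np.isnan(x).any():
            x = np.where(np.isnan(x), np.nanmean(x), x)
        if self.spec.kind == "linear":
            xs = (x - self.params["center"]) / self.params["scale"]
            return np.column_stack([np.ones_like(xs), xs]), rows
        t = self.params["knots"]
        xc = np.clip(x, self.params["lo"], self.params["hi"])
        return BSpline.design_matrix(xc, t, P_SPLINE_DEGREE).toarray(), rows

    def serialize(self):
        out = {
            "param": self.spec.param,
            "kind": self.spec.kind,
            "predictor": self.spec.predictor,
            "cell": [list(cv) for cv in self.spec.cell],
            "coef": self.coef.tolist(),
            "lam": self.lam,
        }
        for key, val in self.params.items():
            out[key] = val.tolist() if isinstance(val, np.ndarray) else val
        return out


def _cell_mask(data, cell):
    mask = np.ones(len(data), dtype=bool)
    for col, val in cell:
        mask &= (data[col] == val).to_numpy()
    return mask


def build_base_learners(
    data,
    family,
    metric_predictors=(),
    binary_predictors=(),
    grouping=(),
    model_sigma_covariates=False,
    covariate_params=None,
):
    """Enumerate candidate learner specs for a predictor table.

    Metric predictors get one P-spline learner per grouping cell, binary
    predictors one linear learner per cell; every distribution parameter gets
    an intercept learner.  By default covariate learners attach to ``mu`` and
    (when the family has one) ``nu``; the scale ``sigma`` is treated as a
    nuisance parameter with an intercept-only predictor unless
    ``model_sigma_covariates`` is set.  Predictors constant within a cell are
    dropped with a warning.
    """
    if covariate_params is None:
        covariate_params = [p for p in family.params if p != "sigma"]
        if model_sigma_covariates:
            covariate_params = list(family.params)
    cells = [()]
    if grouping:
        cells = []
        levels = [sorted(data[g].unique().tolist()) for g in grouping]
        idx = [0] * len(grouping)
        # cartesian product, deterministic order
        import itertools

        for combo in itertools.product(*levels):
            cells.append(tuple(zip(grouping, combo)))

    specs = []
    for param in family.params:
        specs.append(BaseLearnerSpec(param=param, kind="intercept"))
    for param in covariate_params:
        for cell in cells:
            mask = _cell_mask(data, cell)
            for pred in metric_predictors:
                vals = data.loc[mask, pred]
                if vals.nunique(dropna=True) < 2:
                    log.warning("dropping constant predictor %s in cell %s", pred, cell)
                    continue
                specs.append(BaseLearnerSpec(param=param, kind="pspline",
                                             predictor=pred, cell=cell))
            for pred in binary_predictors:
                vals = data.loc[mask, pred]
                if vals.nunique(dropna=True) < 2:
                    log.warning("dropping constant predictor %s in cell %s", pred, cell)
                    continue
                specs.append(BaseLearnerSpec(param=param, kind="linear",
                                             predictor=pred, cell=cell))
    return specs


@dataclass
class BoostModel:
    """A fitted boosting model: offsets plus accumulated learner increments."""

    family_name: str
    shift: float
    response: str
    offsets: dict
    learners: list  # serialized learner dicts
    path: list = field(default_factory=list)  # learner index per iteration
    risks: list = field(default_factory=list)  # training NLL per iteration
    step: float = 0.1
    stopped_early: bool = False

    @property
    def mstop(self):
        return len(self.path)

    @property
    def family(self):
        return family_from_name(self.family_name, shift=self.shift)

    def selected(self):
        """Distinct selected learner names, in first-selection order."""
        seen, out = set(), []
        for idx in self.path:
            if idx not in seen:
                seen.add(idx)
                out.append(_learner_name(self.learners[idx]))
        return out

    def to_dict(self):
        return {
            "family": self.family_name,
            "shift": self.shift,
            "response": self.response,
            "offsets": self.offsets,
            "learners": self.learners,
            "path": list(map(int, self.path)),
            "risks": list(map(float, self.risks)),
            "step": self.step,
            "stopped_early": self.stopped_early,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            family_name=d["family"],
            shift=d["shift"],
            response=d["response"],
            offsets=d["offsets"],
            learners=d["learners"],
            path=d["path"],
            risks=d["risks"],
            step=d["step"],
            stopped_early=d.get("stopped_early", False),
        )


def _learner_name(ser):
    base = ser["predictor"] or "(intercept)"
    cell = ",".join(f"{c}={v}" for c, v in ser["cell"]) if ser["cell"] else "all"
    return f"{ser['param']}~{base}[{cell}]"


def _rebuild_learner_design(ser, data):
    """Design matrix + rows for a serialized learner on arbitrary data."""
    cell = tuple((c, v) for c, v in ser["cell"])
    rows = _cell_mask(data, cell)
    if not rows.any():
        return np.zeros((0, len(ser.get("coef", [1]) or [1]))), rows
    if ser["kind"] == "intercept":
        return np.ones((int(rows.sum()), 1)), rows
    if ser["predictor"] not in data.columns:
        raise KeyError(f"prediction data lacks predictor column {ser['predictor']!r}")
    x = data.loc[rows, ser["predictor"]].to_numpy(dtype=float)
    if np.isnan(x).any():
        x = np.where(np.isnan(x), np.nanmean(x), x)
    if ser["kind"] == "linear":
        xs = (x - ser["center"]) / ser["scale"]
        return np.column_stack([np.ones_like(xs), xs]), rows
    t = np.asarray(ser["knots"])
    xc = np.clip(x, ser["lo"], ser["hi"])
    return BSpline.design_matrix(xc, t, P_SPLINE_DEGREE).toarray(), rows


def boost_fit(
    data,
    response,
    family,
    learners,
    n_iter=100,
    step=0.1,
    df=DEFAULT_DF,
    eval_data=None,
):
    """Fit a boosting model by non-cyclical component-wise gradient descent.

    Parameters
    ----------
    data : predictor table (one row per block x year)
    response : column name in ``data``
    family : a :class:`~savannagrad.families.Family`
    learners : list of :class:`BaseLearnerSpec`
    n_iter, step : iteration budget and step length (shrinkage)
    eval_data : optional held-out table; when given, the per-observation
        out-of-sample NLL after every iteration is returned alongside the model

    The training risk is nonincreasing by construction: when no candidate
    update lowers it the algorithm stops and flags the model.
    """
    if isinstance(family, str):
        family = family_from_name(family)
    y = family.shift_response(data[response].to_numpy(dtype=float))
    n = len(y)
    fitted = [_FittedLearner(spec, data, df_target=df) for spec in learners]
    by_param = {}
    for i, fl in enumerate(fitted):
        by_param.setdefault(fl.spec.param, []).append(i)

    offsets = family.mle_offsets(y)
    eta = {p: np.full(n, offsets[p]) for p in family.params}
    risk = family.nll(y, eta)
    risks = [risk]
    path = []

    track_eval = eval_data is not None
    if track_eval:
        y_ev = family.shift_response(eval_data[response].to_numpy(dtype=float))
        ev_designs = [fl.design_for(eval_data) for fl in fitted]
        eta_ev = {p: np.full(len(y_ev), offsets[p]) for p in family.params}
        eval_risks = [family.nll(y_ev, eta_ev) / len(y_ev)]

    stopped = False
    for _ in range(n_iter):
        theta = family.theta(eta)
        grads = family.gradients(y, theta)
        best = None  # (new_risk, learner_index, coef, fitted_values)
        for param in family.params:
            cand = None  # (sse_score, idx, coef, fit)
            u = grads[param]
            for idx in by_param.get(param, []):
                fl = fitted[idx]
                coef, fit = fl.solve(u)
                # residual improvement over the zero fit, full-vector scale
                score = float(fit @ (2.0 * u[fl.rows] - fit))
                if cand is None or score > cand[0] + 1e-12:
                    cand = (score, idx, coef, fit)
            if cand is None:
                continue
            _, idx, coef, fit = cand
            fl = fitted[idx]
            eta_try = dict(eta)
            new_eta = eta[param].copy()
            new_eta[fl.rows] += step * fit
            eta_try[param] = new_eta
            new_risk = family.nll(y, eta_try)
            if best is None or new_risk < best[0] - 1e-12:
                best = (new_risk, idx, coef, fit)
        if best is None:
            stopped = True
            break
        new_risk, idx, coef, fit = best
        if new_risk > risk + 1e-9:
            stopped = True
            break
        fl = fitted[idx]
        eta[fl.spec.param][fl.rows] += step * fit
        fl.coef += step * coef
        risk = new_risk
        risks.append(risk)
        path.append(idx)
        if track_eval:
            x_ev, rows_ev = ev_designs[idx]
            eta_ev[fl.spec.param][rows_ev] += step * (x_ev @ coef)
            eval_risks.append(family.nll(y_ev, eta_ev) / len(y_ev))

    model = BoostModel(
        family_name=family.name,
        shift=family.shift,
        response=response,
        offsets={p: float(v) for p, v in offsets.items()},
        learners=[fl.serialize() for fl in fitted],
        path=path,
        risks=risks,
        step=step,
        stopped_early=stopped,
    )
    if track_eval:
        return model, np.asarray(eval_risks)
    return model


def predict(model, newdata):
    """Per-parameter predictions on the response scale, plus the overall mean.

    For the zero-adjusted gamma the returned ``mean`` is
    ``(1 - nu) * mu + shift``: the zero part contributes the shift only.
    """
    family = model.family
    n = len(newdata)
    eta = {p: np.full(n, model.offsets[p]) for p in family.params}
    for ser in model.learners:
        coef = np.asarray(ser["coef"])
        if not coef.any():
            continue
        x, rows = _rebuild_learner_design(ser, newdata)
        if rows.any():
            eta[ser["param"]][rows] += x @ coef
    theta = family.theta(eta)
    out = {p: theta[p] for p in family.params}
    out["mean"] = family.mean(theta)
    return out


@dataclass
class CVResult:
    """Out-of-sample risk per (resample, iteration) and the chosen mstop."""

    risks: np.ndarray  # (n_resamples, max_iter + 1)
    mstop: int
    scheme: str
    seed: int

    def mean_curve(self):
        return self.risks.mean(axis=0)


def cv_tune(
    data,
    response,
    family,
    learners,
    max_iter=200,
    step=0.1,
    n_resamples=25,
    train_fraction=0.8,
    stratify=(),
    seed=0,
    df=DEFAULT_DF,
):
    """Tune the stopping iteration by repeated stratified subsampling.

    Each resample holds out ``1 - train_fraction`` of the rows (drawn within
    every stratification cell so all cells stay represented in training),
    refits the boosting path on the remainder and records the held-out mean
    NLL after every iteration; ``mstop`` is the argmin of the column means.
    """
    if isinstance(family, str):
        family = family_from_name(family)
    rng = np.random.default_rng(seed)
    idx_all = np.arange(len(data))
    strata = [idx_all]
    if stratify:
        key = data[list(stratify)].astype(str).agg("|".join, axis=1).to_numpy()
        strata = [idx_all[key == lev] for lev in np.unique(key)]

    rows = []
    for _ in range(n_resamples):
        train_idx = []
        for s in strata:
            perm = rng.permutation(s)
            n_train = max(int(round(train_fraction * len(s))), 1)
            if n_train == len(s) and len(s) > 1:
                n_train -= 1
            train_idx.append(perm[:n_train])
        train_idx = np.sort(np.concatenate(train_idx))
        test_idx = np.setdiff1d(idx_all, train_idx)
        _, ev = boost_fit(
            data.iloc[train_idx],
            response,
            family,
            learners,
            n_iter=max_iter,
            step=step,
            df=df,
            eval_data=data.iloc[test_idx],
        )
        if len(ev) < max_iter + 1:  # early stop: pad with the final risk
            ev = np.concatenate([ev, np.full(max_iter + 1 - len(ev), ev[-1])])
        rows.append(ev)
    risks = np.vstack(rows)
    mstop = int(np.argmin(risks.mean(axis=0)))
    return CVResult(risks=risks, mstop=mstop,
                    scheme=f"subsample({n_resamples}x{train_fraction:.0%})", seed=seed)
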