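"""Stability selection for boosted distributional regression.

Early-stopped boosting offers no p-values, so consistent predictors are
identified by rerunning the selection on complementary half-samples: for each
of ``B/2`` random splits both halves are boosted until ``q_sel`` distinct
covariate learners have been selected, and each learner's selection frequency
is averaged over all ``B`` halves.  A learner is *stable* when its frequency
reaches the threshold ``pi_thr`` (default 0.7, a closed threshold: 0.69 is
out) on the location (``mu``) or zero-part (``nu``) parameter; the scale
``sigma`` is a nuisance parameter whose frequencies are reported but never
confer stability.  The expected number of false selections is bounded by
``PFER <= q_sel^2 / ((2 pi_thr - 1) p)`` with ``p`` the number of candidate
covariate learners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from savannagrad.boost import _FittedLearner, _cell_mask
from savannagrad.families import family_from_name

__all__ = ["StabilityResult", "stabsel", "consistency_report"]

log = logging.getLogger(__name__)

STABILITY_PARAMS = ("mu", "nu")  # sigma never confers stability


@dataclass
class StabilityResult:
    """Selection frequencies and the stable set of one stability-selection run."""

    frequencies: pd.DataFrame  # columns: learner, param, frequency
    b: int
    q_sel: int
    pi_thr: float
    n_candidates: int
    incomplete_runs: int = 0
    label: str = ""

    @property
    def pfer_bound(self):
        return self.q_sel**2 / ((2.0 * self.pi_thr - 1.0) * self.n_candidates)

    @property
    def stable_set(self):
        f = self.frequencies
        hit = f[(f["param"].isin(STABILITY_PARAMS)) & (f["frequency"] >= self.pi_thr)]
        return sorted(hit["learner"].unique().tolist())


def _boost_until(data, response, family, specs, q_sel, step, df, max_iter):
    """Run boosting until q_sel distinct covariate learners are selected.

    Returns (set of selected learner indices restricted to covariate
    learners, reached_flag).  Intercept learners may be updated but do not
    count toward the budget.
    """
    y = family.shift_response(data[response].to_numpy(dtype=float))
    n = len(y)
    fitted = []
    for spec in specs:
        try:
            fitted.append(_FittedLearner(spec, data, df_target=df))
        except ValueError:  # constant within this subsample: skip
            fitted.append(None)
    by_param = {}
    for i, fl in enumerate(fitted):
        if fl is not None:
            by_param.setdefault(fl.spec.param, []).append(i)
    offsets = family.mle_offsets(y)
    eta = {p: np.full(n, offsets[p]) for p in family.params}
    risk = family.nll(y, eta)

    covariate_idx = {i for i, s in enumerate(specs) if s.kind != "intercept"}
    selected = set()
    for _ in range(max_iter):
        theta = family.theta(eta)
        grads = family.gradients(y, theta)
        best = None
        for param in family.params:
            u = grads[param]
            cand = None
            for idx in by_param.get(param, []):
                fl = fitted[idx]
                coef, fit = fl.solve(u)
                score = float(fit @ (2.0 * u[fl.rows] - fit))
                if cand is None or score > cand[0] + 1e-12:
                    cand = (score, idx, fit)
            if cand is None:
                continue
            _, idx, fit = cand
            fl = fitted[idx]
            new_eta = eta[param].copy()
            new_eta[fl.rows] += step * fit
            trial = dict(eta)
            trial[param] = new_eta
            new_risk = family.nll(y, trial)
            if best is None or new_risk < best[0] - 1e-12:
                best = (new_risk, idx, fit)
        if best is None or best[0] > risk + 1e-9:
            return selected, False
        risk, idx, fit = best
        fl = fitted[idx]
        eta[fl.spec.param][fl.rows] += step * fit
        if idx in covariate_idx:
            selected.add(idx)
            if len(selected) >= q_sel:
                return selected, True
    return selected, False


def stabsel(
    data,
    response,
    family,
    learners,
    b=50,
    q_sel=6,
    pi_thr=0.7,
    seed=0,
    step=0.1,
    df=4.0,
    max_iter=1000,
    label="",
):
    """Complementary-pairs stability selection over a learner set.

    Parameters
    ----------
    b : total number of half-samples (must be even; B/2 complementary pairs)
    q_sel : per-run budget of distinct covariate learners
    pi_thr : selection-frequency threshold in (0.5, 1]
    max_iter : iteration cap per run; runs that never reach ``q_sel`` are
        flagged and removed from the frequency denominator
    """
    if isinstance(family, str):
        family = family_from_name(family)
    if b < 2 or b % 2:
        raise ValueError("b must be an even number >= 2 (complementary pairs)")
    if not 0.5 < pi_thr <= 1.0:
        raise ValueError("pi_thr must lie in (0.5, 1]")
    covariate_specs = [s for s in learners if s.kind != "intercept"]
    p = len(covariate_specs)
    if not 1 <= q_sel < p:
        raise ValueError(f"q_sel must lie in 1..{p - 1}")

    rng = np.random.default_rng(seed)
    n = len(data)
    hits = np.zeros(len(learners))
    runs = 0
    incomplete = 0
    for _ in range(b // 2):
        perm = rng.permutation(n)
        halves = (perm[: n // 2], perm[n // 2 : 2 * (n // 2)])
        for half in halves:
            sub = data.iloc[np.sort(half)]
            selected, reached = _boost_until(
                sub, response, family, learners, q_sel, step, df, max_iter
            )
            if not reached:
                incomplete += 1
                log.warning("stability run did not reach q_sel=%d within %d iterations",
                            q_sel, max_iter)
                continue
            runs += 1
            for idx in selected:
                hits[idx] += 1.0

    denom = max(runs, 1)
    rows = []
    for i, spec in enumerate(learners):
        if spec.kind == "intercept":
            continue
        rows.append({
            "learner": spec.predictor,
            "param": spec.param,
            "cell": ",".join(f"{c}={v}" for c, v in spec.cell) if spec.cell else "all",
            "frequency": hits[i] / denom,
        })
    freq = pd.DataFrame(rows)
    return StabilityResult(
        frequencies=freq,
        b=b,
        q_sel=q_sel,
        pi_thr=pi_thr,
        n_candidates=p,
        incomplete_runs=incomplete,
        label=label,
    )


def consistency_report(results):
    """Cross-tabulate stable predictors over analysis cells.

    ``results`` maps a cell label (e.g. ``"reserve/1999"``) to a
    :class:`StabilityResult`.  Scale-parameter frequencies never enter; a
    predictor is *consistent* in a cell when stable for ``mu`` or ``nu``
    there.
    """
    if not results:
        raise ValueError("at least one StabilityResult is required")
    if isinstance(results, StabilityResult):
        results = {results.label or "all": results}
    cells = sorted(results)
    predictors = sorted(
        {p for r in results.values() for p in r.stable_set}
    )
    table = pd.DataFrame(
        [[pred in results[c].stable_set for c in cells] for pred in predictors],
        index=predictors,
        columns=cells,
        dtype=bool,
    )
    table.index.name = "predictor"
    return table
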