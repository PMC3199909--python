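"""Partial credit model: category probabilities, MML-EM calibration, person
scoring (EAP / weighted likelihood), outfit statistics and item filtering.

Estimation is marginal maximum likelihood with an EM algorithm over a fixed
quadrature grid and a normal latent density whose mean and variance are
updated from the posterior each iteration.  Identification: after fitting,
thresholds are re-centered so the mean item location is zero (the latent mean
shifts in the opposite direction, leaving the likelihood untouched).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .data import ItemBank, ResponseMatrix

__all__ = [
    "pcm_category_probs",
    "item_log_probs",
    "expected_score",
    "score_variance",
    "CalibrationResult",
    "fit_pcm",
    "estimate_person_locations",
    "outfit",
    "FilterResult",
    "filter_items",
    "person_separation_index",
]


def item_log_probs(theta: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Log category probabilities, shape (len(theta), m+1).

    log P(X=x | theta) = sum_{k<=x}(theta - delta_k) - log-normalizer,
    with the empty sum for x=0 equal to zero; stabilized via logsumexp.
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    thr = np.asarray(thresholds, float)
    if not np.all(np.isfinite(theta)) or not np.all(np.isfinite(thr)):
        raise ValueError("theta and thresholds must be finite")
    m = thr.size
    cats = np.arange(m + 1)
    cumthr = np.concatenate([[0.0], np.cumsum(thr)])
    logits = theta[:, None] * cats[None, :] - cumthr[None, :]
    return logits - logsumexp(logits, axis=1, keepdims=True)


def pcm_category_probs(theta: float | np.ndarray, thresholds) -> np.ndarray:
    """Probability vector over categories 0..m at one or more trait values.

    Returns shape (m+1,) for scalar ``theta``, else (len(theta), m+1).
    Rows sum to one to machine precision.
    """
    scalar = np.isscalar(theta) or np.asarray(theta).ndim == 0
    probs = np.exp(item_log_probs(theta, thresholds))
    return probs[0] if scalar else probs


def expected_score(theta, thresholds) -> np.ndarray | float:
    """E[X | theta] under the model."""
    probs = np.atleast_2d(pcm_category_probs(theta, thresholds))
    cats = np.arange(probs.shape[1])
    ev = probs @ cats
    return float(ev[0]) if np.isscalar(theta) or np.asarray(theta).ndim == 0 else ev


def score_variance(theta, thresholds) -> np.ndarray | float:
    """Var[X | theta]; equals the item Fisher information for this model."""
    probs = np.atleast_2d(pcm_category_probs(theta, thresholds))
    cats = np.arange(probs.shape[1])
    ev = probs @ cats
    ev2 = probs @ cats**2
    out = ev2 - ev**2
    return float(out[0]) if np.isscalar(theta) or np.asarray(theta).ndim == 0 else out


# ---------------------------------------------------------------------------
# MML-EM calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Fitted PCM: item parameters, person scores and fit diagnostics."""

    bank: ItemBank                       # thresholds = estimates, re-centered
    threshold_se: list[np.ndarray]
    person_ids: np.ndarray
    person_theta: np.ndarray             # EAP under the fitted latent density
    person_se: np.ndarray
    latent_mu: float
    latent_sigma: float
    loglik: float
    ll_path: np.ndarray
    converged: bool
    n_iterations: int
    psi: float
    outfit: np.ndarray | None = None     # aligned with bank.ids
    removed_items: list[tuple[int, float]] = field(default_factory=list)
    category_maps: dict[int, np.ndarray] = field(default_factory=dict)
    quadrature: tuple[int, float, float] = (61, -6.0, 6.0)

    @property
    def item_locations(self) -> np.ndarray:
        return self.bank.locations


def _collapse_categories(resp: np.ndarray, ncat: int, item_id: int):
    """Map observed categories to contiguous 0..K-1; warn when collapsing."""
    obs = resp[resp >= 0]
    seen = np.unique(obs).astype(int)
    if seen.size < 2:
        raise ValueError(
            f"item {item_id}: fewer than 2 observed categories; cannot calibrate"
        )
    if seen.size == ncat and seen[-1] == ncat - 1:
        return resp, None
    warnings.warn(
        f"item {item_id}: categories {sorted(set(range(ncat)) - set(seen))} never "
        "observed; collapsing to contiguous scores",
        stacklevel=3,
    )
    remap = np.full(ncat, -1, int)
    remap[seen] = np.arange(seen.size)
    # unseen categories map to the nearest lower observed one
    for c in range(ncat):
        if remap[c] < 0:
            lower = seen[seen < c]
            remap[c] = remap[lower[-1]] if lower.size else 0
    out = resp.copy()
    mask = resp >= 0
    out[mask] = remap[resp[mask]]
    return out, remap


def _mstep_item(r: np.ndarray, nodes: np.ndarray, thr: np.ndarray,
                max_newton: int = 50, gtol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Maximize the expected complete-data log-likelihood for one item.

    ``r`` is (Q, K): expected response counts per node and category.  The
    objective is concave in the thresholds, so damped Newton converges.
    Returns (thresholds, information matrix at the solution).
    """
    thr = thr.copy()
    m = thr.size
    n_q = r.sum(axis=1)  # expected persons per node

    def grad_hess(t):
        p = np.exp(item_log_probs(nodes, t))  # (Q, K)
        # P(X >= j) for j = 1..m
        tail = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]  # (Q, m)
        r_tail = np.cumsum(r[:, ::-1], axis=1)[:, ::-1][:, 1:]  # observed >= j
        g = (n_q[:, None] * tail - r_tail).sum(axis=0)
        # Hessian of the log-likelihood: -sum_q n_q Cov_q(ind_j, ind_l)
        cov = np.einsum("q,qj,ql->jl", n_q, tail, tail)
        mx = np.maximum.outer(np.arange(1, m + 1), np.arange(1, m + 1))
        tail_mx = np.concatenate([tail, np.zeros((len(nodes), 1))], axis=1)
        pmax = np.einsum("q,qjl->jl", n_q, tail_mx[:, mx - 1])
        H = cov - pmax
        return g, H

    def objective(t):
        lp = item_log_probs(nodes, t)
        return float((r * lp).sum())

    f = objective(thr)
    for _ in range(max_newton):
        g, H = grad_hess(thr)
        if np.max(np.abs(g)) < gtol:
            break
        try:
            step = np.linalg.solve(H - 1e-12 * np.eye(m), g)
        except np.linalg.LinAlgError:
            step = g / (np.abs(np.diag(H)).max() + 1e-12)
        new = thr - step
        f_new = objective(new)
        shrink = 0
        while f_new < f - 1e-12 and shrink < 30:  # backtrack (concavity guard)
            step *= 0.5
            new = thr - step
            f_new = objective(new)
            shrink += 1
        thr, f = new, f_new
    _, H = grad_hess(thr)
    return thr, -H


def fit_pcm(
    responses: ResponseMatrix,
    bank: ItemBank | None = None,
    quadrature_nodes: int = 61,
    node_range: tuple[float, float] = (-6.0, 6.0),
    max_iter: int = 500,
    tol: float = 1e-6,
) -> CalibrationResult:
    """Calibrate a PCM on a (possibly structurally incomplete) matrix.

    Missing responses are treated as missing-by-design (ignorable): they
    simply contribute nothing to the likelihood.  ``bank`` supplies item
    metadata (blocks, labels, category counts); when absent, categories are
    inferred from the data.
    """
    if bank is None:
        ncat = np.nanmax(responses.values, axis=0).astype(int) + 1
        bank = ItemBank(
            ids=responses.item_ids,
            labels=[f"item{j}" for j in responses.item_ids],
            blocks=np.array(["A"] * responses.n_items, object),
            thresholds=[np.zeros(max(int(c) - 1, 1)) for c in ncat],
            retained=np.ones(responses.n_items, bool),
        )
    bank = bank.subset(responses.item_ids)
    responses.validate_against(bank)

    n_persons, n_items = responses.values.shape
    resp = np.where(np.isnan(responses.values), -1, responses.values).astype(int)

    # collapse never-observed categories; reject single-category items
    category_maps: dict[int, np.ndarray] = {}
    ncats = bank.n_categories.copy()
    for j in range(n_items):
        resp[:, j], remap = _collapse_categories(resp[:, j], ncats[j], int(bank.ids[j]))
        if remap is not None:
            category_maps[int(bank.ids[j])] = remap
            ncats[j] = int(resp[:, j][resp[:, j] >= 0].max()) + 1

    kmax = int(ncats.max())
    nodes = np.linspace(node_range[0], node_range[1], quadrature_nodes)
    mu, sigma = 0.0, 1.0
    thresholds = [np.linspace(-0.5, 0.5, ncats[j] - 1) if ncats[j] > 2 else np.zeros(1)
                  for j in range(n_items)]

    # indicator stacks for fast E-step matmuls: ind[c] is (N, I)
    ind = [(resp == c) for c in range(kmax)]

    ll_path = []
    converged = False
    it = 0
    W = None
    for it in range(1, max_iter + 1):
        # E-step: log P(response row | node)
        logp_items = np.full((n_items, quadrature_nodes, kmax), -np.inf)
        for j in range(n_items):
            logp_items[j, :, : ncats[j]] = item_log_probs(nodes, thresholds[j])
        person_node_ll = np.zeros((n_persons, quadrature_nodes))
        for c in range(kmax):
            lp_c = logp_items[:, :, c]  # (I, Q); -inf only where category absent
            lp_c = np.where(np.isfinite(lp_c), lp_c, 0.0)
            person_node_ll += ind[c] @ lp_c
        log_prior = norm.logpdf(nodes, mu, sigma)
        log_prior -= logsumexp(log_prior)
        log_joint = person_node_ll + log_prior[None, :]
        log_marg = logsumexp(log_joint, axis=1)
        ll = float(log_marg.sum())
        ll_path.append(ll)
        W = np.exp(log_joint - log_marg[:, None])  # posterior node weights

        if len(ll_path) > 1 and abs(ll - ll_path[-2]) < tol * (abs(ll_path[-2]) + 1.0):
            converged = True
            break

        # M-step: latent moments from the posterior, thresholds per item
        mu = float((W @ nodes).mean())
        sigma = float(np.sqrt(max((W @ nodes**2).mean() - mu**2, 1e-6)))
        for j in range(n_items):
            r = np.stack([ind[c][:, j] @ W for c in range(ncats[j])], axis=1)
            thresholds[j], _ = _mstep_item(r, nodes, thresholds[j], max_newton=5)

    # standard errors from the (expected) information at the solution
    threshold_se = []
    info_mats = []
    for j in range(n_items):
        r = np.stack([ind[c][:, j] @ W for c in range(ncats[j])], axis=1)
        thr_j, info = _mstep_item(r, nodes, thresholds[j], max_newton=50)
        thresholds[j] = thr_j
        info_mats.append(info)
        try:
            se = np.sqrt(np.diag(np.linalg.inv(info)))
        except np.linalg.LinAlgError:
            se = np.full(thr_j.size, np.nan)
        threshold_se.append(se)

    # identification: mean item location zero; latent mean shifts with it
    center = float(np.mean([t.mean() for t in thresholds]))
    thresholds = [t - center for t in thresholds]
    mu -= center
    nodes_c = nodes - center  # same quadrature, expressed on the centered scale

    fitted = bank.with_thresholds(thresholds)
    # EAP person scores on the centered scale (posterior weights are invariant)
    theta_eap = W @ nodes_c
    se_eap = np.sqrt(np.maximum(W @ nodes_c**2 - theta_eap**2, 0.0))

    wle_theta, wle_se = estimate_person_locations(
        responses, fitted, method="wle"
    )
    psi = person_separation_index(wle_theta, wle_se)

    return CalibrationResult(
        bank=fitted,
        threshold_se=threshold_se,
        person_ids=responses.person_ids.copy(),
        person_theta=theta_eap,
        person_se=se_eap,
        latent_mu=mu,
        latent_sigma=sigma,
        loglik=ll_path[-1],
        ll_path=np.asarray(ll_path),
        converged=converged,
        n_iterations=it,
        psi=psi,
        category_maps=category_maps,
        quadrature=(quadrature_nodes, node_range[0] - center, node_range[1] - center),
    )


# ---------------------------------------------------------------------------
# Person scoring
# ---------------------------------------------------------------------------


def _test_information(theta_grid: np.ndarray, thresholds: list[np.ndarray],
                      observed_cols: np.ndarray) -> np.ndarray:
    info = np.zeros_like(theta_grid)
    for j in observed_cols:
        info += score_variance(theta_grid, thresholds[j])
    return info


def estimate_person_locations(
    responses: ResponseMatrix,
    bank: ItemBank,
    method: str = "eap",
    latent: tuple[float, float] = (0.0, 1.0),
    quadrature_nodes: int = 61,
    node_range: tuple[float, float] = (-6.0, 6.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Batch person-location estimates and standard errors.

    ``eap``: posterior mean/SD over a fixed grid under a normal latent
    density.  ``wle``: Warm-type weighted likelihood — for this model the
    penalized objective loglik + 0.5*log(test information), maximized on a
    fine grid; finite at extreme score patterns, SE = 1/sqrt(information).
    """
    bank = bank.subset(responses.item_ids)
    observed = responses.observed
    if not observed.any(axis=1).all():
        bad = responses.person_ids[~observed.any(axis=1)].tolist()
        raise ValueError(f"persons with zero observed responses: {bad}")
    resp = np.where(observed, responses.values, -1).astype(int)
    n_persons, n_items = resp.shape

    if method == "eap":
        nodes = np.linspace(node_range[0], node_range[1], quadrature_nodes)
    elif method == "wle":
        nodes = np.linspace(node_range[0] - 2.0, node_range[1] + 2.0, 4 * quadrature_nodes + 1)
    else:
        raise ValueError(f"unknown scoring method: {method}")

    kmax = int(bank.n_categories.max())
    logp_items = np.zeros((n_items, len(nodes), kmax))
    for j in range(n_items):
        lp = item_log_probs(nodes, bank.thresholds[j])
        logp_items[j, :, : lp.shape[1]] = lp
    person_node_ll = np.zeros((n_persons, len(nodes)))
    for c in range(kmax):
        person_node_ll += (resp == c) @ logp_items[:, :, c]

    if method == "eap":
        mu, sigma = latent
        log_prior = norm.logpdf(nodes, mu, sigma)
        log_prior -= logsumexp(log_prior)
        log_post = person_node_ll + log_prior[None, :]
        log_post -= logsumexp(log_post, axis=1, keepdims=True)
        Wp = np.exp(log_post)
        theta = Wp @ nodes
        se = np.sqrt(np.maximum(Wp @ nodes**2 - theta**2, 1e-300))
        return theta, se

    # WLE
    theta = np.empty(n_persons)
    se = np.empty(n_persons)
    info_cache: dict[frozenset, np.ndarray] = {}
    for n in range(n_persons):
        cols = np.flatnonzero(observed[n])
        key = frozenset(cols.tolist())
        if key not in info_cache:
            info_cache[key] = _test_information(nodes, bank.thresholds, cols)
        info = info_cache[key]
        penalized = person_node_ll[n] + 0.5 * np.log(np.maximum(info, 1e-300))
        i_best = int(np.argmax(penalized))
        # parabolic refinement around the grid maximum
        if 0 < i_best < len(nodes) - 1:
            y0, y1, y2 = penalized[i_best - 1 : i_best + 2]
            denom = y0 - 2 * y1 + y2
            offset = 0.5 * (y0 - y2) / denom if denom < -1e-12 else 0.0
            step = nodes[1] - nodes[0]
            theta[n] = nodes[i_best] + np.clip(offset, -1, 1) * step
        else:
            theta[n] = nodes[i_best]
        se[n] = 1.0 / np.sqrt(max(float(np.interp(theta[n], nodes, info)), 1e-300))
    return theta, se


# ---------------------------------------------------------------------------
# Fit statistics and filtering
# ---------------------------------------------------------------------------


def apply_category_maps(
    responses: ResponseMatrix, category_maps: dict[int, np.ndarray]
) -> ResponseMatrix:
    """Re-express raw responses on the collapsed category scale of a fit."""
    if not category_maps:
        return responses
    vals = responses.values.copy()
    for item_id, remap in category_maps.items():
        pos = np.flatnonzero(responses.item_ids == item_id)
        if pos.size == 0:
            continue
        j = int(pos[0])
        mask = ~np.isnan(vals[:, j])
        vals[mask, j] = remap[vals[mask, j].astype(int)]
    return ResponseMatrix(vals, responses.person_ids.copy(),
                          responses.item_ids.copy(), responses.design)


def outfit(
    responses: ResponseMatrix,
    bank: ItemBank,
    person_theta: np.ndarray,
) -> np.ndarray:
    """Unweighted mean-square of standardized residuals per item.

    outfit_i = mean over observed responses of
    ((x - E[x|theta]) / sd[x|theta])^2.  Responses at numerically degenerate
    trait values (variance ~ 0) are excluded with a warning.
    """
    bank = bank.subset(responses.item_ids)
    theta = np.asarray(person_theta, float)
    out = np.full(responses.n_items, np.nan)
    for j in range(responses.n_items):
        mask = responses.observed[:, j]
        if not mask.any():
            continue
        th = theta[mask]
        x = responses.values[mask, j]
        ev = expected_score(th, bank.thresholds[j])
        var = score_variance(th, bank.thresholds[j])
        ok = var > 1e-12
        if not ok.all():
            warnings.warn(
                f"item {bank.ids[j]}: {np.sum(~ok)} responses at degenerate "
                "variance excluded from outfit",
                stacklevel=2,
            )
        if not ok.any():
            continue
        z2 = (x[ok] - ev[ok]) ** 2 / var[ok]
        out[j] = float(z2.mean())
    return out


@dataclass
class FilterResult:
    bank: ItemBank                      # full bank, retained flags updated
    removed: list[tuple[int, float]]    # (item_id, outfit)
    calibration: CalibrationResult      # refit on retained items when possible


def filter_items(
    calibration: CalibrationResult,
    responses: ResponseMatrix | None = None,
    threshold: float = 1.7,
) -> FilterResult:
    """Drop items with outfit >= ``threshold``; refit on the survivors.

    ``calibration.outfit`` must be populated (or ``responses`` given so it can
    be computed here).  When ``responses`` is provided the PCM is refit once on
    the retained items so final parameters exclude misfitting items.
    """
    if threshold <= 0:
        raise ValueError("outfit threshold must be positive")
    fit_vals = calibration.outfit
    if fit_vals is None:
        if responses is None:
            raise ValueError("outfit not computed and no responses supplied")
        fit_vals = outfit(
            apply_category_maps(responses, calibration.category_maps),
            calibration.bank, calibration.person_theta,
        )
        calibration.outfit = fit_vals

    bank = calibration.bank.copy()
    removed = [
        (int(bank.ids[j]), float(fit_vals[j]))
        for j in range(len(bank))
        if np.isfinite(fit_vals[j]) and fit_vals[j] >= threshold
    ]
    removed_ids = {i for i, _ in removed}
    bank.retained = np.array([i not in removed_ids for i in bank.ids])

    if removed and responses is not None:
        kept = bank.ids[bank.retained]
        mapped = apply_category_maps(responses, calibration.category_maps)
        refit = fit_pcm(
            mapped.subset_items(kept),
            bank.subset(kept),
            quadrature_nodes=calibration.quadrature[0],
        )
        # compose collapse maps so refit maps apply to raw responses
        merged = dict(calibration.category_maps)
        for item_id, m2 in refit.category_maps.items():
            m1 = merged.get(item_id)
            merged[item_id] = m2 if m1 is None else m2[m1]
        refit.category_maps = merged
        refit.removed_items = removed
        refit.outfit = outfit(
            apply_category_maps(responses.subset_items(kept), refit.category_maps),
            refit.bank, refit.person_theta,
        )
        return FilterResult(bank=bank, removed=removed, calibration=refit)
    calibration.removed_items = removed
    return FilterResult(bank=bank, removed=removed, calibration=calibration)


def person_separation_index(theta: np.ndarray, se: np.ndarray) -> float:
    """PSI = (Var(theta_hat) - mean(SE^2)) / Var(theta_hat).

    Can be negative for uninformative tests; that value is returned as-is.
    """
    theta = np.asarray(theta, float)
    se = np.asarray(se, float)
    if theta.size < 2:
        raise ValueError("PSI needs at least two persons")
    var = float(np.var(theta, ddof=1))
    if var <= 0:
        raise ValueError("PSI undefined: zero variance of person estimates")
    return (var - float(np.mean(se**2))) / var
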