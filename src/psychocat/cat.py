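"""Adaptive-testing engine: Fisher-information item selection, grid-based
Bayesian trait updating under a right-skewed (shifted lognormal) prior, and
stopping rules including the clinical-decision rule (stop once the confidence
interval around the trait estimate clears a fixed cutoff).

The simulation replays stored questionnaire answers as if they were given
adaptively: a person's item pool contains only items they actually answered.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .data import ItemBank, ResponseMatrix
from .pcm import item_log_probs, pcm_category_probs

__all__ = [
    "item_information",
    "GridPrior",
    "lognormal_prior",
    "normal_prior",
    "posterior_update",
    "select_next_item",
    "StoppingRule",
    "CatTrace",
    "run_cat",
    "simulate_cat_cohort",
]


def item_information(theta: float, thresholds) -> float:
    """Fisher information of one item at ``theta``: Var[X | theta]."""
    probs = pcm_category_probs(float(theta), thresholds)
    cats = np.arange(len(probs))
    ev = float(probs @ cats)
    return float(probs @ cats**2) - ev * ev


@dataclass
class GridPrior:
    """A discretized prior: support grid plus normalized point masses."""

    grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.mass = np.asarray(self.mass, float)
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.mass.shape != self.grid.shape:
            raise ValueError("mass must align with grid")

    @property
    def mean(self) -> float:
        return float(self.mass @ self.grid)

    @property
    def sd(self) -> float:
        return float(np.sqrt(max(self.mass @ self.grid**2 - self.mean**2, 0.0)))


def _normalize_on_grid(grid: np.ndarray, density: np.ndarray) -> np.ndarray:
    # trapezoid quadrature weights turn densities into point masses
    w = np.empty_like(grid)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2
    w[0] = (grid[1] - grid[0]) / 2
    w[-1] = (grid[-1] - grid[-2]) / 2
    mass = density * w
    total = mass.sum()
    if total <= 0:
        raise ValueError("prior density is zero everywhere on the grid")
    return mass / total


def lognormal_prior(grid: np.ndarray, shift: float = -4.0, mu: float = 0.5,
                    sigma: float = 0.6) -> GridPrior:
    """Shifted-lognormal prior masses on ``grid``: zero at or below ``shift``,
    density lognormal(theta - shift; mu, sigma) above it."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    grid = np.asarray(grid, float)
    if np.all(grid <= shift):
        raise ValueError("grid lies entirely at or below the support shift")
    x = grid - shift
    density = np.zeros_like(grid)
    pos = x > 0
    density[pos] = np.exp(-((np.log(x[pos]) - mu) ** 2) / (2 * sigma**2)) / (
        x[pos] * sigma * np.sqrt(2 * np.pi)
    )
    return GridPrior(grid, _normalize_on_grid(grid, density))


def normal_prior(grid: np.ndarray, mu: float = 0.0, sigma: float = 1.0) -> GridPrior:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    grid = np.asarray(grid, float)
    return GridPrior(grid, _normalize_on_grid(grid, norm.pdf(grid, mu, sigma)))


def default_grid(shift: float = -4.0, upper: float = 6.0, n_nodes: int = 61) -> np.ndarray:
    return np.linspace(shift + 1e-6, upper, n_nodes)


def posterior_update(
    administered: list[tuple[int, int]],
    bank: ItemBank,
    prior: GridPrior,
) -> tuple[float, float, np.ndarray]:
    """Grid posterior given (item_id, response) pairs.

    Returns (posterior mean, posterior SD, posterior masses).  Likelihood is
    accumulated in log space.
    """
    log_post = np.log(np.maximum(prior.mass, 1e-300))
    log_post[prior.mass <= 0] = -np.inf
    for item_id, resp in administered:
        j = bank.index_of(item_id)
        lp = item_log_probs(prior.grid, bank.thresholds[j])
        m = bank.n_categories[j] - 1
        if not (0 <= resp <= m):
            raise ValueError(f"response {resp} outside 0..{m} for item {item_id}")
        log_post += lp[:, int(resp)]
    z = logsumexp(log_post)
    if not np.isfinite(z):
        raise ValueError("posterior numerically zero: grid/prior mismatch")
    post = np.exp(log_post - z)
    mean = float(post @ prior.grid)
    sd = float(np.sqrt(max(post @ prior.grid**2 - mean**2, 0.0)))
    return mean, sd, post


class _BankTables:
    """Precomputed per-bank arrays for fast, exact CAT arithmetic.

    Items are grouped by category count so information at a scalar theta is
    one vectorized softmax per group; log-prob tables on the prior grid make
    posterior updates a single slice-add.
    """

    def __init__(self, bank: ItemBank, grid: np.ndarray | None = None):
        self.bank = bank
        self.id_to_pos = {int(i): j for j, i in enumerate(bank.ids)}
        ncat = bank.n_categories
        self.groups = []
        for K in np.unique(ncat):
            pos = np.flatnonzero(ncat == K)
            cumthr = np.stack(
                [np.concatenate([[0.0], np.cumsum(bank.thresholds[j])]) for j in pos]
            )
            self.groups.append((pos, np.arange(K, dtype=float), cumthr))
        if grid is not None:
            kmax = int(ncat.max())
            self.logp = np.full((len(bank), len(grid), kmax), -np.inf)
            for j in range(len(bank)):
                lp = item_log_probs(grid, bank.thresholds[j])
                self.logp[j, :, : lp.shape[1]] = lp
        else:
            self.logp = None

    def information(self, theta: float) -> np.ndarray:
        """Exact Fisher information of every item at scalar ``theta``."""
        out = np.empty(len(self.bank))
        for pos, cats, cumthr in self.groups:
            logits = theta * cats[None, :] - cumthr
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            ev = p @ cats
            out[pos] = p @ cats**2 - ev**2
        return out


def select_next_item(theta_hat: float, bank: ItemBank,
                     available_ids: np.ndarray,
                     tables: _BankTables | None = None) -> int:
    """Most informative available item at ``theta_hat``; ties -> smallest id."""
    available_ids = np.asarray(available_ids, int)
    if available_ids.size == 0:
        raise ValueError("item pool exhausted")
    if tables is None:
        tables = _BankTables(bank)
    order = np.sort(available_ids)
    info_all = tables.information(float(theta_hat))
    info = info_all[[tables.id_to_pos[int(i)] for i in order]]
    return int(order[int(np.argmax(info))])


@dataclass
class StoppingRule:
    """One of three stopping rules.

    ``fixed_n``: administer exactly ``k`` items.  ``precision``: stop when
    1.96*SE <= ``halfwidth``.  ``decision``: stop "above"/"below" as soon as
    the confidence interval around the estimate excludes ``cutoff``;
    "undecided" at ``max_items`` or pool exhaustion.
    """

    kind: str
    k: int | None = None
    halfwidth: float | None = None
    cutoff: float | None = None
    confidence: float = 0.95
    max_items: int = 100

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_n", "precision", "decision"):
            raise ValueError(f"unknown stopping rule kind: {self.kind}")
        if self.kind == "fixed_n" and (self.k is None or self.k < 1):
            raise ValueError("fixed_n rule needs k >= 1")
        if self.kind == "precision" and (self.halfwidth is None or self.halfwidth <= 0):
            raise ValueError("precision rule needs a positive halfwidth")
        if self.kind == "decision" and self.cutoff is None:
            raise ValueError("decision rule needs a cutoff")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if self.max_items < 1:
            raise ValueError("max_items must be >= 1")

    @classmethod
    def fixed_n(cls, k: int, cutoff: float | None = None) -> "StoppingRule":
        return cls(kind="fixed_n", k=k, cutoff=cutoff)

    @classmethod
    def precision(cls, halfwidth: float, cutoff: float | None = None,
                  max_items: int = 100) -> "StoppingRule":
        return cls(kind="precision", halfwidth=halfwidth, cutoff=cutoff,
                   max_items=max_items)

    @classmethod
    def decision(cls, cutoff: float, confidence: float = 0.95,
                 max_items: int = 100) -> "StoppingRule":
        return cls(kind="decision", cutoff=cutoff, confidence=confidence,
                   max_items=max_items)


@dataclass
class CatTrace:
    """One person's adaptive-testing trajectory and final decision."""

    person_id: int
    administered: list[int]
    responses: list[int]
    theta_path: list[float]
    se_path: list[float]
    theta_hat: float
    se: float
    decision: str  # {"above", "below", "undecided"}
    n_items: int
    rule: StoppingRule
    seed: int

    def to_record(self) -> dict:
        return {
            "person_id": self.person_id,
            "rule": self.rule.kind,
            "n_items": self.n_items,
            "theta_hat": self.theta_hat,
            "se": self.se,
            "decision": self.decision,
            "administered": ";".join(str(i) for i in self.administered),
        }


def _classify(theta: float, se: float, rule: StoppingRule) -> str:
    """Side of the cutoff by point estimate (used when no CI is required)."""
    if rule.cutoff is None:
        return "undecided"
    return "above" if theta >= rule.cutoff else "below"


def run_cat(
    person_responses: dict[int, int],
    bank: ItemBank,
    rule: StoppingRule,
    prior: GridPrior,
    seed: int = 0,
    person_id: int = -1,
    _tables: _BankTables | None = None,
) -> CatTrace:
    """Replay one person's stored answers adaptively.

    ``person_responses`` maps item id -> stored response; only those items are
    in this person's pool.  The first item is drawn uniformly at random
    (seeded); afterwards items maximize Fisher information at the current
    estimate and the posterior is refreshed after every answer.
    """
    known = set(bank.ids.tolist())
    pool = sorted(int(i) for i in person_responses if i in known)
    if not pool:
        raise ValueError(f"person {person_id}: empty item pool")
    rng = np.random.default_rng(seed)
    z = norm.ppf(1 - (1 - rule.confidence) / 2)
    if _tables is None or _tables.logp is None:
        _tables = _BankTables(bank, grid=prior.grid)

    administered: list[int] = []
    responses: list[int] = []
    theta_path: list[float] = []
    se_path: list[float] = []
    available = list(pool)

    next_item = int(available[rng.integers(len(available))])
    theta_hat, se = prior.mean, prior.sd
    decision = "undecided"
    budget = rule.k if rule.kind == "fixed_n" else rule.max_items

    log_post = np.log(np.maximum(prior.mass, 1e-300))
    log_post[prior.mass <= 0] = -np.inf
    grid = prior.grid

    while True:
        resp = int(person_responses[next_item])
        administered.append(next_item)
        responses.append(resp)
        available.remove(next_item)
        log_post = log_post + _tables.logp[_tables.id_to_pos[next_item], :, resp]
        zc = logsumexp(log_post)
        if not np.isfinite(zc):
            raise ValueError("posterior numerically zero: grid/prior mismatch")
        post = np.exp(log_post - zc)
        theta_hat = float(post @ grid)
        se = float(np.sqrt(max(post @ grid**2 - theta_hat**2, 0.0)))
        theta_path.append(theta_hat)
        se_path.append(se)

        if rule.kind == "fixed_n":
            if len(administered) >= min(rule.k, len(pool)):
                decision = _classify(theta_hat, se, rule)
                break
        elif rule.kind == "precision":
            if 1.96 * se <= rule.halfwidth:
                decision = _classify(theta_hat, se, rule)
                break
            if len(administered) >= min(budget, len(pool)):
                decision = _classify(theta_hat, se, rule)
                break
        else:  # decision rule
            lo, hi = theta_hat - z * se, theta_hat + z * se
            if rule.cutoff < lo:
                decision = "above"
                break
            if rule.cutoff > hi:
                decision = "below"
                break
            if len(administered) >= min(rule.max_items, len(pool)):
                decision = "undecided"
                break

        next_item = select_next_item(theta_hat, bank, np.array(available), _tables)

    return CatTrace(
        person_id=person_id,
        administered=administered,
        responses=responses,
        theta_path=theta_path,
        se_path=se_path,
        theta_hat=theta_hat,
        se=se,
        decision=decision,
        n_items=len(administered),
        rule=rule,
        seed=seed,
    )


def simulate_cat_cohort(
    responses: ResponseMatrix,
    bank: ItemBank,
    rule: StoppingRule,
    prior: GridPrior,
    seed: int = 0,
) -> list[CatTrace]:
    """Run the CAT for every person; per-person seeds spawn from ``seed``."""
    pool_bank = bank.retained_bank()
    keep = np.isin(responses.item_ids, pool_bank.ids)
    child_seeds = np.random.SeedSequence(seed).spawn(responses.n_persons)
    tables = _BankTables(pool_bank, grid=prior.grid)
    traces = []
    for n in range(responses.n_persons):
        row = responses.values[n]
        stored = {
            int(responses.item_ids[j]): int(row[j])
            for j in np.flatnonzero(keep & ~np.isnan(row))
        }
        pid = int(responses.person_ids[n])
        if not stored:
            raise ValueError(f"person {pid}: no stored responses on retained items")
        traces.append(
            run_cat(
                stored,
                pool_bank,
                rule,
                prior,
                seed=int(child_seeds[n].generate_state(1)[0]),
                person_id=pid,
                _tables=tables,
            )
        )
    return traces
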