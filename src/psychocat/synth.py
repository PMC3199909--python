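"""Synthetic cohorts: item banks, populations and structurally incomplete
response matrices mirroring a screening-survey design.

The design has one long core block (A) answered by everyone and three short
blocks (B, C, D) each answered by roughly a third of the cohort.  The latent
trait is right-skewed (shifted lognormal): few problems are common, severe
problems rare.  The criterion score is the block-A sum score, and "clinical"
means strictly above the cohort's 90th percentile of that score.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import BLOCKS, ItemBank, PairedBank, ResponseMatrix, validate_persons
from .pcm import pcm_category_probs

__all__ = [
    "generate_item_bank",
    "generate_population",
    "generate_responses",
    "score_criterion",
    "inject_dif",
    "generate_study",
]

# logistic-link defaults make treatment a deliberately weak criterion
TREATMENT_INTERCEPT = -2.7
TREATMENT_SLOPE = 0.55


def generate_item_bank(
    n_core: int = 118,
    n_short: int = 25,
    n_categories: int = 3,
    location_low: float = -2.0,
    location_high: float = 3.0,
    spread: float = 1.0,
    seed: int = 0,
) -> ItemBank:
    """Draw an item bank: ``n_core`` block-A items plus ``n_short`` in each of
    B, C and D.

    Item locations are uniform on ``[location_low, location_high]``;
    thresholds are the location plus centered, sorted offsets whose range is
    controlled by ``spread``.  Every item starts retained.
    """
    if n_core < 1 or n_short < 1:
        raise ValueError("item counts must be positive")
    if n_categories < 2:
        raise ValueError("need at least 2 response categories")
    if not location_low < location_high:
        raise ValueError("location_low must be below location_high")
    if spread <= 0:
        raise ValueError("spread must be positive")
    rng = np.random.default_rng(seed)
    counts = {"A": n_core, "B": n_short, "C": n_short, "D": n_short}
    ids, labels, blocks, thresholds = [], [], [], []
    i = 0
    m = n_categories - 1
    for block in BLOCKS:
        for k in range(counts[block]):
            loc = rng.uniform(location_low, location_high)
            if m == 1:
                offs = np.zeros(1)
            else:
                offs = np.sort(rng.uniform(-spread, spread, size=m))
                offs = offs - offs.mean()
            ids.append(i)
            labels.append(f"{block}{k + 1:03d}")
            blocks.append(block)
            thresholds.append(loc + offs)
            i += 1
    return ItemBank(
        ids=np.array(ids),
        labels=labels,
        blocks=np.array(blocks, object),
        thresholds=thresholds,
        retained=np.ones(len(ids), bool),
    )


def generate_population(
    n_persons: int = 2041,
    theta_shift: float = -4.0,
    lognorm_mu: float = 0.5,
    lognorm_sigma: float = 0.6,
    treatment_slope: float = TREATMENT_SLOPE,
    treatment_intercept: float = TREATMENT_INTERCEPT,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a person table with a right-skewed latent trait.

    theta_true = theta_shift + lognormal(mu, sigma).  Treatment status is a
    noisy logistic function of the trait so it discriminates materially worse
    than the criterion score.  Criterion fields are filled later by
    :func:`score_criterion`.
    """
    if n_persons < 1:
        raise ValueError("n_persons must be positive")
    if lognorm_sigma <= 0:
        raise ValueError("lognorm_sigma must be positive")
    rng = np.random.default_rng(seed)
    theta = theta_shift + rng.lognormal(lognorm_mu, lognorm_sigma, size=n_persons)
    gender = rng.integers(0, 2, size=n_persons)
    ethnicity = rng.integers(0, 2, size=n_persons)
    p_treat = expit(treatment_intercept + treatment_slope * theta)
    treated = rng.random(n_persons) < p_treat
    assigned = rng.choice(["B", "C", "D"], size=n_persons)
    return pd.DataFrame(
        {
            "id": np.arange(n_persons),
            "theta_true": theta,
            "gender": gender,
            "ethnicity": ethnicity,
            "assigned_block": assigned,
            "criterion_score": np.full(n_persons, np.nan),
            "clinical": np.full(n_persons, False),
            "treated": treated,
        }
    )


def _draw_item_responses(rng, theta: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    probs = pcm_category_probs(theta, thresholds)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(theta))
    return (u[:, None] > cum[:, :-1]).sum(axis=1)


def generate_responses(
    bank: ItemBank | PairedBank,
    persons: pd.DataFrame,
    design: str = "four_block",
    seed: int = 0,
) -> ResponseMatrix:
    """Sample PCM responses at each person's true trait.

    ``four_block`` gives every person block A plus their assigned short
    block; ``complete`` observes everything.  Accepts a :class:`PairedBank`
    (uniform DIF injected for one group) transparently.
    """
    paired = isinstance(bank, PairedBank)
    base = bank.base if paired else bank
    if len(base) == 0 or len(persons) == 0:
        raise ValueError("bank and persons must be nonempty")
    validate_persons(persons, require_theta=True)
    if design not in ("complete", "four_block"):
        raise ValueError(f"unknown design: {design}")

    rng = np.random.default_rng(seed)
    theta = persons["theta_true"].to_numpy(float)
    n, p = len(persons), len(base)
    values = np.full((n, p), np.nan)

    if design == "complete":
        observed = np.ones((n, p), bool)
    else:
        observed = np.zeros((n, p), bool)
        observed[:, np.asarray(base.blocks) == "A"] = True
        assigned = persons["assigned_block"].to_numpy()
        for blk in ("B", "C", "D"):
            rows = assigned == blk
            observed[np.ix_(rows, np.asarray(base.blocks) == blk)] = True

    group = (
        persons[bank.group].to_numpy(int) if paired else np.zeros(n, int)
    )
    for j in range(p):
        mask = observed[:, j]
        if not mask.any():
            continue
        if paired and base.ids[j] == bank.item_id:
            thr0 = bank.bank_for(0).thresholds[j]
            thr1 = bank.bank_for(1).thresholds[j]
            draws = np.empty(n)
            g = group == 1
            # two seeded sub-draws, order fixed by group membership
            u = rng.random(n)
            for thr, rows in ((thr0, mask & ~g), (thr1, mask & g)):
                if rows.any():
                    probs = pcm_category_probs(theta[rows], thr)
                    cum = np.cumsum(probs, axis=1)
                    draws[rows] = (u[rows, None] > cum[:, :-1]).sum(axis=1)
            values[mask, j] = draws[mask]
        else:
            values[mask, j] = _draw_item_responses(rng, theta[mask], base.thresholds[j])
    return ResponseMatrix(values, persons["id"].to_numpy(int), base.ids.copy(), design)


def score_criterion(responses: ResponseMatrix, bank: ItemBank,
                    persons: pd.DataFrame) -> pd.DataFrame:
    """Fill criterion_score (block-A sum) and the clinical flag.

    clinical = score strictly above the cohort's empirical 90th percentile
    (linear-interpolation quantile); ties with the percentile resolve to
    "not clinical".
    """
    bank = bank.subset(responses.item_ids)
    core_cols = np.flatnonzero(np.asarray(bank.blocks) == "A")
    if core_cols.size == 0:
        raise ValueError("bank has no block-A items to score")
    core = responses.values[:, core_cols]
    if np.isnan(core).any():
        bad = responses.person_ids[np.isnan(core).any(axis=1)]
        raise ValueError(f"missing block-A responses for persons: {bad.tolist()}")
    score = core.sum(axis=1).astype(int)
    cut = np.quantile(score, 0.9)  # linear interpolation
    out = persons.copy()
    order = pd.Series(np.arange(len(responses.person_ids)), index=responses.person_ids)
    idx = order.loc[out["id"]].to_numpy()
    out["criterion_score"] = score[idx]
    out["clinical"] = score[idx] > cut
    return out


def inject_dif(bank: ItemBank, item_id: int, group: str, shift: float) -> PairedBank:
    """Pair the bank with a variant where ``item_id``'s thresholds are shifted
    by ``shift`` logits for group==1 persons (uniform DIF)."""
    return PairedBank(base=bank, item_id=item_id, group=group, shift=shift)


def generate_study(
    n_persons: int = 2041,
    bank_kwargs: dict | None = None,
    population_kwargs: dict | None = None,
    design: str = "four_block",
    seed: int = 0,
):
    """Convenience: bank + population + responses + criterion in one call."""
    ss = np.random.SeedSequence(seed)
    s_bank, s_pop, s_resp = (int(c.generate_state(1)[0]) for c in ss.spawn(3))
    bank = generate_item_bank(seed=s_bank, **(bank_kwargs or {}))
    persons = generate_population(n_persons=n_persons, seed=s_pop,
                                  **(population_kwargs or {}))
    responses = generate_responses(bank, persons, design=design, seed=s_resp)
    persons = score_criterion(responses, bank, persons)
    return bank, persons, responses
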