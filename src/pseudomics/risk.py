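"""Matched extreme polygenic-risk groups.

For each trait, the 20 donors with the highest and the 20 with the lowest
PRS form candidate pools; a logistic propensity model on age, brain pH, PMI
and RIN followed by greedy 1:1 nearest-neighbor matching on the logit
propensity — with sex matched exactly — trims the pools to balanced,
equal-sized high- and low-risk groups. Both groups typically mix cases and
controls, since extreme genetic risk neither guarantees nor precludes
diagnosis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "RiskGroupAssignment",
    "select_extreme_candidates",
    "estimate_propensity",
    "greedy_match_exact_sex",
    "define_risk_groups",
]

PROPENSITY_COVARIATES = ("age", "brain_pH", "pmi", "rin")


@dataclass
class RiskGroupAssignment:
    """Final matched groups for one trait plus balance diagnostics."""

    trait: str
    table: pd.DataFrame  # donor_id, group(high/low/excluded), propensity, pair_id
    balance: pd.DataFrame  # covariate, smd_pre, smd_post
    mixes_cases_and_controls: dict[str, bool]

    def donors(self, group: str) -> list[str]:
        t = self.table
        return sorted(t.loc[t["group"] == group, "donor_id"])

    def assignment_frame(self) -> pd.DataFrame:
        """donor_id/group frame consumed by the differential-testing stage."""
        return self.table.loc[self.table["group"] != "excluded", ["donor_id", "group"]]


def select_extreme_candidates(
    cohort_prs: pd.DataFrame, trait: str, n_extreme: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top and bottom ``n_extreme`` donors by PRS.

    Ties spanning the pool boundary are broken by ascending donor_id and
    logged, so selection is deterministic.
    """
    if trait not in cohort_prs.columns:
        raise ValueError(f"trait {trait!r} not present in the cohort/PRS table")
    n = len(cohort_prs)
    if n < 2 * n_extreme:
        raise ValueError(f"{n} donors cannot supply two pools of {n_extreme}")
    # one global ranking keeps the pools disjoint even under boundary ties
    ranked = cohort_prs.sort_values(
        [trait, "donor_id"], ascending=[False, True], kind="mergesort"
    )
    high = ranked.head(n_extreme)
    low = ranked.tail(n_extreme).iloc[::-1]  # ascending PRS first
    for pool, name in ((high, "high"), (low, "low")):
        boundary = pool[trait].iloc[-1]
        n_tied = int((cohort_prs[trait] == boundary).sum())
        if n_tied > int((pool[trait] == boundary).sum()):
            logger.info(
                "PRS tie at the %s-pool boundary (%g); broken by donor_id", name, boundary
            )
    return high.reset_index(drop=True), low.reset_index(drop=True)


def estimate_propensity(
    candidates: pd.DataFrame,
    group_label: np.ndarray | pd.Series,
    covariates: tuple[str, ...] = PROPENSITY_COVARIATES,
) -> np.ndarray:
    """Propensity of high-group membership from a logistic regression.

    Sex is not in the model (it is matched exactly). Constant covariates
    are dropped with a warning. Under complete separation or non-convergence
    the fallback scores donors by a linear discriminant on standardized
    covariates passed through the logistic function. Scores are clipped
    away from 0 and 1 so the logit distance stays finite.
    """
    y = np.asarray(group_label, dtype=float)
    cols = []
    names = []
    for cov in covariates:
        x = candidates[cov].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"covariate {cov!r} has missing values; impute first")
        if x.std(ddof=0) == 0:
            warnings.warn(f"constant covariate {cov!r} dropped from the propensity model")
            continue
        cols.append((x - x.mean()) / x.std(ddof=0))
        names.append(cov)
    if not cols:
        return np.full(len(candidates), 0.5)
    Z = np.column_stack(cols)
    X = sm.add_constant(Z)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False) or np.abs(fit.params).max() > 50:
            raise np.linalg.LinAlgError("separation")
        scores = np.asarray(fit.predict(X))
    except Exception:
        warnings.warn(
            "propensity regression did not converge (likely separation); "
            "falling back to a linear discriminant on standardized covariates"
        )
        w = Z[y == 1].mean(axis=0) - Z[y == 0].mean(axis=0)
        scores = expit(Z @ w)
    return np.clip(scores, 1e-6, 1 - 1e-6)


def greedy_match_exact_sex(
    high: pd.DataFrame,
    low: pd.DataFrame,
    high_propensity: np.ndarray,
    low_propensity: np.ndarray,
) -> list[tuple[str, str]]:
    """1:1 greedy nearest-neighbor matching on logit propensity, sex-exact.

    Within each sex stratum, high-group donors are processed in descending
    propensity order; each takes the unmatched low-group donor minimizing
    the absolute logit-propensity distance (ties broken by donor_id).
    Unmatched donors are excluded. Returns (high_donor, low_donor) pairs.
    """
    pairs: list[tuple[str, str]] = []
    hp = pd.Series(logit(high_propensity), index=high["donor_id"].to_numpy())
    lp = pd.Series(logit(low_propensity), index=low["donor_id"].to_numpy())
    h_sex = pd.Series(high["sex"].to_numpy(), index=high["donor_id"].to_numpy())
    l_sex = pd.Series(low["sex"].to_numpy(), index=low["donor_id"].to_numpy())
    for sex in sorted(set(h_sex) | set(l_sex)):
        h_ids = [d for d in hp.index if h_sex[d] == sex]
        l_ids = [d for d in lp.index if l_sex[d] == sex]
        h_ids.sort(key=lambda d: (-hp[d], d))  # descending propensity
        available = set(l_ids)
        for hd in h_ids:
            if not available:
                break
            best = min(available, key=lambda ld: (abs(hp[hd] - lp[ld]), ld))
            pairs.append((hd, best))
            available.discard(best)
    return pairs


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with pooled SD."""
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def define_risk_groups(
    cohort: pd.DataFrame,
    prs: pd.DataFrame,
    trait: str,
    n_extreme: int = 20,
    covariates: tuple[str, ...] = PROPENSITY_COVARIATES,
) -> RiskGroupAssignment:
    """Candidates -> propensity -> exact-sex matching -> balance table.

    The returned groups are equal-sized by construction, every matched pair
    shares a sex, and the balance table reports pre- and post-matching SMDs
    for the propensity covariates.
    """
    merged = cohort.merge(prs, on="donor_id", validate="one_to_one")
    if merged[list(covariates)].isna().any().any():
        from .covariates import impute_rin

        merged = impute_rin(merged)
    high, low = select_extreme_candidates(merged, trait, n_extreme)
    candidates = pd.concat([high, low], ignore_index=True)
    labels = np.r_[np.ones(len(high)), np.zeros(len(low))]
    prop = estimate_propensity(candidates, labels, covariates)
    hp, lp = prop[: len(high)], prop[len(high):]
    # discard donors outside the common support of the two propensity
    # distributions before pairing; poor-overlap extremes cannot be matched
    # credibly and would freeze the imbalance into the final groups
    lo_b, hi_b = max(hp.min(), lp.min()), min(hp.max(), lp.max())
    h_keep, l_keep = (hp >= lo_b) & (hp <= hi_b), (lp >= lo_b) & (lp <= hi_b)
    if not (h_keep.all() and l_keep.all()):
        logger.info(
            "common-support discard: %d high / %d low candidates outside overlap",
            int((~h_keep).sum()), int((~l_keep).sum()),
        )
    pairs = greedy_match_exact_sex(
        high.loc[h_keep], low.loc[l_keep], hp[h_keep], lp[l_keep]
    )
    matched_high = {h for h, _ in pairs}
    matched_low = {l for _, l in pairs}
    assert len(matched_high) == len(matched_low) == len(pairs)

    prop_map = dict(zip(candidates["donor_id"], prop))
    pair_of = {}
    for i, (h, l) in enumerate(sorted(pairs)):
        pair_of[h] = i
        pair_of[l] = i
    rows = []
    for _, rec in candidates.iterrows():
        d = rec["donor_id"]
        if d in matched_high:
            grp = "high"
        elif d in matched_low:
            grp = "low"
        else:
            grp = "excluded"
        rows.append(
            {
                "donor_id": d,
                "group": grp,
                "propensity": prop_map[d],
                "pair_id": pair_of.get(d, -1),
            }
        )
    table = pd.DataFrame(rows).sort_values("donor_id").reset_index(drop=True)

    sex_of = dict(zip(candidates["donor_id"], candidates["sex"]))
    for h, l in pairs:
        assert sex_of[h] == sex_of[l], "exact-sex matching violated"

    cand_idx = candidates.set_index("donor_id")
    balance_rows = []
    for cov in covariates:
        pre = _smd(
            cand_idx.loc[high["donor_id"], cov].to_numpy(dtype=float),
            cand_idx.loc[low["donor_id"], cov].to_numpy(dtype=float),
        )
        if pairs:
            post = _smd(
                cand_idx.loc[sorted(matched_high), cov].to_numpy(dtype=float),
                cand_idx.loc[sorted(matched_low), cov].to_numpy(dtype=float),
            )
        else:
            post = np.nan
        balance_rows.append({"covariate": cov, "smd_pre": pre, "smd_post": post})

    mixes = {}
    for grp, members in (("high", matched_high), ("low", matched_low)):
        statuses = set(cand_idx.loc[sorted(members), "disease_status"]) if members else set()
        mixes[grp] = len(statuses) > 1
    logger.info(
        "trait %s: %d matched pairs; high/low mix cases and controls: %s",
        trait, len(pairs), mixes,
    )
    return RiskGroupAssignment(
        trait=trait,
        table=table,
        balance=pd.DataFrame(balance_rows),
        mixes_cases_and_controls=mixes,
    )
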