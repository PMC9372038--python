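"""Per-chromosome Gaussian-mixture clustering of projected QTL peaks.

The model treats each projected peak x_i as drawn from one of K meta-QTL
components: x_i | k ~ Normal(mu_k, sigma_i^2), where sigma_i is *known* per
observation, derived from the projected 95% CI (sigma_i = CI width / 3.92,
floored). Free parameters are the K component means and K-1 mixing weights
(d = 2K - 1). The number of components is chosen in two steps: fit K = 1..Kmax
by EM, then take the K achieving the minimum in at least three of five
information criteria (AIC, AICc, AIC3, BIC, AWE); if no K reaches three
votes, fall back to the BIC-minimal K (tie at equal votes -> smaller K).

Fitted components become MQTLs: each QTL joins its maximum-posterior
component when that posterior clears ``assign_threshold`` (else it is
reported *unassigned*); one-member components are *singletons*; components
whose members all come from a single mapping study are discarded as
single-study hotspots. Survivors are named MQTL<chrom>.<rank> in ascending
position. The MQTL position is the inverse-variance-weighted mean of member
peaks, and its 95% CI is position +/- 1.96 / sqrt(sum 1/sigma_i^2) -- the
pooling that shrinks the interval relative to any single member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .projection import ProjectedQTL

SIGMA_FLOOR_CM = 0.05
CI95_TO_SIGMA = 3.92  # two-sided 95% normal interval spans 2 * 1.96 sigma

CRITERIA = ("AIC", "AICc", "AIC3", "BIC", "AWE")


def sigma_from_ci(ci_width_cm: float, floor: float = SIGMA_FLOOR_CM) -> float:
    """Per-observation sd implied by a 95% CI width, floored."""
    return max(float(ci_width_cm) / CI95_TO_SIGMA, floor)


@dataclass
class MixtureFit:
    K: int
    weights: np.ndarray          # (K,), sums to 1
    means: np.ndarray            # (K,), ascending
    sigmas: np.ndarray           # (n,) per-observation sd
    positions: np.ndarray        # (n,) observed peaks
    loglik: float
    posteriors: np.ndarray       # (n, K)
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self):
        assert abs(float(self.weights.sum()) - 1.0) < 1e-9


def _log_density(x, sigmas, means):
    """(n, K) matrix of log N(x_i | mu_k, sigma_i^2)."""
    z = (x[:, None] - means[None, :]) / sigmas[:, None]
    return -0.5 * z**2 - np.log(sigmas)[:, None] - 0.5 * math.log(2 * math.pi)


def _em(x, sigmas, means0, tol=1e-8, max_iter=2000):
    K = len(means0)
    means = np.array(means0, dtype=float)
    weights = np.full(K, 1.0 / K)
    prev = -np.inf
    inv_var = 1.0 / sigmas**2
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        logp = _log_density(x, sigmas, means) + np.log(weights)[None, :]
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        r = np.exp(logp - norm[:, None])
        weights = r.mean(axis=0)
        weights = np.clip(weights, 1e-12, None)
        weights /= weights.sum()
        denom = (r * inv_var[:, None]).sum(axis=0)
        num = (r * (x * inv_var)[:, None]).sum(axis=0)
        means = np.where(denom > 0, num / np.clip(denom, 1e-300, None), means)
        if ll - prev < tol and n_iter > 1:
            converged = True
            prev = ll
            break
        prev = ll
    order = np.argsort(means, kind="stable")
    logp = _log_density(x, sigmas, means[order]) + np.log(weights[order])[None, :]
    norm = logsumexp(logp, axis=1)
    post = np.exp(logp - norm[:, None])
    return MixtureFit(
        K=K,
        weights=weights[order],
        means=means[order],
        sigmas=sigmas,
        positions=x,
        loglik=float(norm.sum()),
        posteriors=post,
        n_iter=n_iter,
        converged=converged,
    )


def fit_gaussian_mixture(
    positions: Sequence[float],
    sigmas: Sequence[float],
    K: int,
    seeds: int = 5,
    rng: np.random.Generator | int | None = 0,
    sigma_floor: float = SIGMA_FLOOR_CM,
) -> MixtureFit:
    """EM fit of the known-variance K-component mixture; best of restarts.

    Initial means are placed at the quantile spread of the observations; each
    additional restart jitters them with seeded noise. Raises ValueError when
    K exceeds the number of observations.
    """
    x = np.asarray(positions, dtype=float)
    s = np.maximum(np.asarray(sigmas, dtype=float), sigma_floor)
    n = len(x)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError("K exceeds n")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    q = np.quantile(x, (np.arange(K) + 0.5) / K)
    spread = max(x.max() - x.min(), 1e-6)
    best = None
    for trial in range(max(1, seeds)):
        init = q if trial == 0 else np.sort(q + rng.normal(0, 0.05 * spread, size=K))
        fit = _em(x, s, init)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


# ---------------------------------------------------------------------------
# Model-selection criteria
# ---------------------------------------------------------------------------


def classification_loglik(fit: MixtureFit) -> float:
    """Log-likelihood under hard maximum-posterior assignment."""
    z = fit.posteriors.argmax(axis=1)
    logp = _log_density(fit.positions, fit.sigmas, fit.means)
    return float((logp[np.arange(len(z)), z] + np.log(fit.weights[z])).sum())


def compute_criteria(fit: MixtureFit, n: int | None = None) -> dict:
    """AIC / AICc / AIC3 / BIC / AWE for one fitted K.

    d = 2K - 1 free parameters (K means, K-1 weights; variances are known).
    AICc is undefined (NaN) when n - d - 1 <= 0 and is then excluded from
    the vote. AWE uses the classification log-likelihood.
    """
    n = len(fit.positions) if n is None else n
    d = 2 * fit.K - 1
    ll = fit.loglik
    aic = -2 * ll + 2 * d
    aicc = aic + 2 * d * (d + 1) / (n - d - 1) if n - d - 1 > 0 else float("nan")
    aic3 = -2 * ll + 3 * d
    bic = -2 * ll + d * math.log(n)
    llc = classification_loglik(fit)
    awe = -2 * llc + 2 * d * (1.5 + math.log(n))
    return {"K": fit.K, "AIC": aic, "AICc": aicc, "AIC3": aic3, "BIC": bic, "AWE": awe}


def criteria_table(fits: Sequence[MixtureFit]) -> pd.DataFrame:
    n = len(fits[0].positions)
    return pd.DataFrame([compute_criteria(f, n) for f in fits]).set_index("K")


def select_model(table: pd.DataFrame) -> tuple[int, dict]:
    """K achieving the minimum in >= 3 of the 5 criteria.

    Falls back to the BIC-minimal K when no K collects three votes; ties at
    equal votes resolve to the smaller K. Returns (K*, vote detail).
    """
    votes: dict[int, int] = {}
    winners = {}
    for crit in CRITERIA:
        col = table[crit].dropna()
        if col.empty:
            continue
        k = int(col.idxmin())
        winners[crit] = k
        votes[k] = votes.get(k, 0) + 1
    detail = {"votes": votes, "winners": winners, "rule": "vote"}
    if votes:
        top = max(votes.values())
        if top >= 3:
            ks = sorted(k for k, v in votes.items() if v == top)
            return ks[0], detail
    detail["rule"] = "bic_fallback"
    return int(table["BIC"].dropna().idxmin()), detail


# ---------------------------------------------------------------------------
# MQTL formation
# ---------------------------------------------------------------------------

#: The six stress classes a locus can confer tolerance to (combined "D+H"
#: records expand into DS and HS for tallying).
STRESS_CLASSES = ("DS", "HS", "SS", "WS", "PHS", "AS")


def expand_stress(code: str) -> tuple[str, ...]:
    return ("DS", "HS") if code == "D+H" else (code,)


@dataclass
class MQTL:
    name: str
    chromosome: str
    position_cm: float
    ci_start_cm: float
    ci_end_cm: float
    member_ids: tuple
    n_studies: int
    mean_lod: float
    mean_pve: float
    stress_tally: dict = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def n_stress_classes(self) -> int:
        return sum(1 for c in STRESS_CLASSES if self.stress_tally.get(c, 0) > 0)

    @property
    def ci_width_cm(self) -> float:
        return self.ci_end_cm - self.ci_start_cm


def stress_tally(members: Sequence[ProjectedQTL]) -> dict:
    tally: dict[str, int] = {}
    for m in members:
        for c in expand_stress(m.source.stress):
            tally[c] = tally.get(c, 0) + 1
    return tally


def form_mqtls(
    fit: MixtureFit,
    members: Sequence[ProjectedQTL],
    chromosome: str,
    assign_threshold: float = 0.5,
    pve_weighting: str = "mean",
) -> tuple[list[MQTL], dict]:
    """Turn mixture components into named MQTLs; account for every QTL.

    Returns (mqtls, discards) where discards maps reason ->
    list of qtl ids / component indices: "unassigned" (max posterior below
    threshold), "singleton" (one-member component), "single_study"
    (all members from one study).
    """
    assert len(members) == len(fit.positions)
    z = fit.posteriors.argmax(axis=1)
    pmax = fit.posteriors.max(axis=1)
    discards: dict = {"unassigned": [], "singleton": [], "single_study": []}
    comp_members: dict[int, list[int]] = {k: [] for k in range(fit.K)}
    for i, m in enumerate(members):
        if pmax[i] >= assign_threshold:
            comp_members[int(z[i])].append(i)
        else:
            discards["unassigned"].append(m.source.qtl_id)

    survivors = []
    for k in range(fit.K):
        idx = comp_members[k]
        if not idx:
            continue
        mem = [members[i] for i in idx]
        ids = [m.source.qtl_id for m in mem]
        if len(idx) == 1:
            discards["singleton"].extend(ids)
            continue
        studies = {m.source.study_id for m in mem}
        if len(studies) < 2:
            discards["single_study"].extend(ids)
            continue
        xs = fit.positions[idx]
        ws = 1.0 / fit.sigmas[idx] ** 2
        pos = float(np.sum(xs * ws) / np.sum(ws))
        half = 1.96 / math.sqrt(float(np.sum(ws)))
        lods = [m.source.lod for m in mem if m.source.lod is not None]
        if pve_weighting == "posterior":
            pw = fit.posteriors[idx, k]
            pves = [m.source.pve for m in mem]
            mean_pve = float(np.average(pves, weights=pw)) if pves else float("nan")
        else:
            pves = [m.source.pve for m in mem if m.source.pve is not None]
            mean_pve = float(np.mean(pves)) if pves else float("nan")
        survivors.append(
            MQTL(
                name="",
                chromosome=chromosome,
                position_cm=pos,
                ci_start_cm=pos - half,
                ci_end_cm=pos + half,
                member_ids=tuple(ids),
                n_studies=len(studies),
                mean_lod=float(np.mean(lods)) if lods else float("nan"),
                mean_pve=mean_pve,
                stress_tally=stress_tally(mem),
            )
        )
    survivors.sort(key=lambda m: m.position_cm)
    for rank, m in enumerate(survivors, start=1):
        m.name = f"MQTL{chromosome}.{rank}"
    return survivors, discards


def analyze_chromosome(
    projected: Sequence[ProjectedQTL],
    chromosome: str,
    k_max: int | None = None,
    seeds: int = 5,
    rng: np.random.Generator | int | None = 0,
    assign_threshold: float = 0.5,
) -> dict:
    """Fit K = 1..Kmax, vote, and form MQTLs for one chromosome.

    Returns a dict with keys: mqtls, discards, criteria, k_selected,
    selection_detail, fit.
    """
    members = [p for p in projected if p.projected and p.consensus_chromosome == chromosome]
    if not members:
        return {
            "mqtls": [],
            "discards": {},
            "criteria": pd.DataFrame(),
            "k_selected": 0,
            "selection_detail": {},
            "fit": None,
        }
    x = [p.peak_cm for p in members]
    s = [sigma_from_ci(p.ci_width_cm) for p in members]
    n = len(x)
    k_max = min(n, 10) if k_max is None else min(k_max, n)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fits = [fit_gaussian_mixture(x, s, K, seeds=seeds, rng=rng) for K in range(1, k_max + 1)]
    table = criteria_table(fits)
    k_star, detail = select_model(table)
    fit = fits[k_star - 1]
    mqtls, discards = form_mqtls(fit, members, chromosome, assign_threshold)
    return {
        "mqtls": mqtls,
        "discards": discards,
        "criteria": table,
        "k_selected": k_star,
        "selection_detail": detail,
        "fit": fit,
    }


def mqtls_to_frame(mqtls: Sequence[MQTL]) -> pd.DataFrame:
    rows = []
    for m in mqtls:
        row = {
            "name": m.name,
            "chromosome": m.chromosome,
            "position_cm": m.position_cm,
            "ci_start_cm": m.ci_start_cm,
            "ci_end_cm": m.ci_end_cm,
            "n_members": m.n_members,
            "n_studies": m.n_studies,
            "mean_lod": m.mean_lod,
            "mean_pve": m.mean_pve,
            "n_stress_classes": m.n_stress_classes,
            "members": ";".join(m.member_ids),
        }
        for c in STRESS_CLASSES:
            row[f"n_{c}"] = m.stress_tally.get(c, 0)
        rows.append(row)
    return pd.DataFrame(rows)
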