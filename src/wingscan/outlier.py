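"""Per-locus differentiation scans.

Three complementary statistics over a two-group genotype matrix:

* ``wc_fst`` — the Weir–Cockerham variance-components θ̂ per locus.
* ``bayescan_fit`` — a hierarchical Bayesian logistic-FST model with a
  reversible-jump MCMC over locus-specific selection effects.  For locus *i*
  and group *j* the alternate-allele count is beta-binomial,

      a_ij ~ BetaBin(n_ij, θ_ij p_i, θ_ij (1 − p_i)),   θ_ij = 1/FST_ij − 1,
      logit(FST_ij) = δ_i α_i + β_j,

  with p_i ~ U(0,1), α_i ~ N(0,1), β_j ~ N(−1,1) and prior inclusion odds
  Pr(δ=0)/Pr(δ=1) given by ``prior_odds_neutral``.  A locus's posterior
  inclusion probability P_i is converted to a q-value (expected false
  discovery rate of the list of loci at least as extreme).
* ``pcadapt_scan`` — regression of each standardized SNP on the leading
  principal components, robust Mahalanobis distance of the z-statistics,
  genomic-inflation rescaling and Benjamini–Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, expit
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

from .genotype import GenotypeMatrix


@dataclass
class MCMCConfig:
    """Sampler settings for :func:`bayescan_fit`.

    Defaults are the study-scale settings (10,000 output iterations at
    thinning 10, burn-in 10,000, 20 pilot runs of 10,000 and prior odds 10
    for the neutral model).  :meth:`reduced` returns the fast profile used
    by the test-suite simulations.
    """

    n_output: int = 10000
    thinning: int = 10
    burn_in: int = 10000
    n_pilot: int = 20
    pilot_length: int = 10000
    prior_odds_neutral: float = 10.0
    seed: int | None = None

    def validate(self) -> None:
        for name in ("n_output", "thinning", "burn_in", "n_pilot", "pilot_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.prior_odds_neutral <= 0:
            raise ValueError("prior_odds_neutral must be positive")

    @classmethod
    def reduced(cls, seed: int | None = None) -> "MCMCConfig":
        """Short-chain profile for simulation-based tests."""
        return cls(n_output=400, thinning=2, burn_in=400, n_pilot=4,
                   pilot_length=200, prior_odds_neutral=10.0, seed=seed)

    def with_seed(self, seed: int) -> "MCMCConfig":
        return replace(self, seed=seed)


@dataclass
class OutlierResult:
    """Per-locus posterior summaries of one Bayesian scan."""

    table: pd.DataFrame  # locus_id index: posterior_prob, alpha_mean, fst_g1, fst_g2, q_value
    beta_mean: np.ndarray  # per-group posterior mean of β_j
    group_levels: list[str]
    diagnostics: pd.DataFrame  # iteration, log_posterior, n_included
    dropped_loci: list[str] = field(default_factory=list)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.table.index)

    def outlier_set(self, q_threshold: float = 0.2) -> set[str]:
        """Loci with q-value at or below the threshold."""
        return set(self.table.index[self.table["q_value"] <= q_threshold])

    def top_locus(self) -> str:
        """The most significantly differentiated locus (smallest q, then
        largest posterior probability, then id)."""
        t = self.table
        order = np.lexsort(
            (np.asarray(t.index), -t["posterior_prob"].to_numpy(), t["q_value"].to_numpy())
        )
        return str(t.index[order[0]])


# ---------------------------------------------------------------------------
# Weir–Cockerham FST
# ---------------------------------------------------------------------------


def wc_fst(gm: GenotypeMatrix, groups: list[str] | None = None) -> np.ndarray:
    """Per-locus Weir–Cockerham θ̂ between groups.

    Computed from the variance components a (among groups), b (among
    individuals within groups) and c (within individuals); loci whose
    denominator is undefined (e.g. monomorphic, or a group with no calls)
    return NaN.
    """
    levels = groups if groups is not None else gm.group_levels
    r = len(levels)
    if r < 2:
        raise ValueError("wc_fst requires at least two groups")
    labels = np.asarray(gm.group_labels)
    called = gm.called_mask()
    calls = gm.calls

    n_i = np.zeros((gm.n_loci, r))  # individuals called, per group
    p_i = np.zeros((gm.n_loci, r))  # alt-allele frequency, per group
    h_i = np.zeros((gm.n_loci, r))  # het proportion, per group
    for j, lev in enumerate(levels):
        rows = labels == lev
        cj = called[rows]
        n = cj.sum(axis=0)
        alt = np.where(cj, calls[rows], 0).sum(axis=0)
        het = ((calls[rows] == 1) & cj).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n_i[:, j] = n
            p_i[:, j] = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
            h_i[:, j] = np.where(n > 0, het / np.maximum(n, 1), np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.mean(axis=1)
        nsum = n_i.sum(axis=1)
        nc = (nsum - (n_i**2).sum(axis=1) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=1) / nsum
        s2 = (n_i * (p_i - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=1) / nsum

        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta = np.where(np.abs(denom) > 0, a / denom, np.nan)
    bad = (n_i == 0).any(axis=1) | ~np.isfinite(denom)
    theta = np.where(bad, np.nan, theta)
    return theta


# ---------------------------------------------------------------------------
# Bayesian logistic-FST model with RJ-MCMC
# ---------------------------------------------------------------------------


def _bb_loglik(a, n, p, theta):
    """Beta-binomial log likelihood up to the fixed binomial coefficient."""
    u = theta * p
    v = theta * (1.0 - p)
    return betaln(a + u, n - a + v) - betaln(u, v)


class _BayescanState:
    """Mutable sampler state; all per-locus moves are vectorized."""

    def __init__(self, a, n, cfg: MCMCConfig, rng: np.random.Generator):
        self.a = a.astype(float)  # (L, 2)
        self.n = n.astype(float)
        self.L = a.shape[0]
        self.J = a.shape[1]
        self.cfg = cfg
        self.rng = rng
        with np.errstate(divide="ignore", invalid="ignore"):
            init_p = (a.sum(axis=1) + 0.5) / (n.sum(axis=1) + 1.0)
        self.p = np.clip(init_p, 1e-4, 1 - 1e-4)
        self.alpha = np.zeros(self.L)
        self.delta = np.zeros(self.L, dtype=bool)
        self.beta = np.full(self.J, -1.0)
        # proposal widths (tuned by pilots)
        self.w_p = np.full(self.L, 0.2)
        self.w_a = np.full(self.L, 0.5)
        self.w_b = np.full(self.J, 0.2)
        self.ll = self._loglik_all()
        self.log_po = np.log(cfg.prior_odds_neutral)

    # -- likelihood helpers ------------------------------------------------
    def _theta(self, alpha=None, delta=None, beta=None):
        alpha = self.alpha if alpha is None else alpha
        delta = self.delta if delta is None else delta
        beta = self.beta if beta is None else beta
        x = delta[:, None] * alpha[:, None] + beta[None, :]
        return np.exp(-x)  # θ = 1/FST − 1 with FST = sigmoid(x)

    def _loglik_all(self, p=None, alpha=None, delta=None, beta=None):
        p = self.p if p is None else p
        return _bb_loglik(self.a, self.n, p[:, None], self._theta(alpha, delta, beta))

    # -- moves ---------------------------------------------------------------
    def update_p(self, track=None):
        prop = self.p + self.w_p * self.rng.standard_normal(self.L)
        # reflect into (0, 1): symmetric proposal, uniform prior
        prop = np.abs(prop)
        prop = np.where(prop > 1.0, 2.0 - prop, prop)
        ok = (prop > 0.0) & (prop < 1.0)
        prop = np.where(ok, prop, self.p)
        ll_new = _bb_loglik(self.a, self.n, prop[:, None], self._theta())
        delta_ll = ll_new.sum(axis=1) - self.ll.sum(axis=1)
        acc = ok & (np.log(self.rng.random(self.L)) < delta_ll)
        self.p = np.where(acc, prop, self.p)
        self.ll = np.where(acc[:, None], ll_new, self.ll)
        if track is not None:
            track["p"] += acc

    def update_alpha(self, track=None):
        idx = np.where(self.delta)[0]
        if idx.size == 0:
            return
        prop = self.alpha[idx] + self.w_a[idx] * self.rng.standard_normal(idx.size)
        theta = np.exp(-(prop[:, None] + self.beta[None, :]))
        ll_new = _bb_loglik(self.a[idx], self.n[idx], self.p[idx, None], theta)
        delta_ll = ll_new.sum(axis=1) - self.ll[idx].sum(axis=1)
        log_prior = 0.5 * (self.alpha[idx] ** 2 - prop**2)  # N(0,1) prior ratio
        acc = np.log(self.rng.random(idx.size)) < delta_ll + log_prior
        upd = idx[acc]
        self.alpha[upd] = prop[acc]
        self.ll[upd] = ll_new[acc]
        if track is not None:
            track["alpha"][upd] += 1
            track["alpha_n"][idx] += 1

    def update_delta(self):
        """Reversible-jump toggle of each locus's inclusion indicator.

        The locus effect is proposed from its N(0,1) prior, so prior and
        proposal densities cancel and the acceptance ratio reduces to the
        likelihood ratio times the prior-odds factor."""
        alpha_birth = self.rng.standard_normal(self.L)
        cand_alpha = np.where(self.delta, self.alpha, alpha_birth)
        cand_delta = ~self.delta
        ll_new = self._loglik_all(alpha=cand_alpha, delta=cand_delta)
        delta_ll = ll_new.sum(axis=1) - self.ll.sum(axis=1)
        log_acc = delta_ll + np.where(self.delta, self.log_po, -self.log_po)
        acc = np.log(self.rng.random(self.L)) < log_acc
        self.alpha = np.where(acc & cand_delta, cand_alpha, self.alpha)
        self.delta = np.where(acc, cand_delta, self.delta)
        self.ll = np.where(acc[:, None], ll_new, self.ll)

    def update_beta(self, track=None):
        for j in range(self.J):
            prop = self.beta.copy()
            prop[j] = prop[j] + self.w_b[j] * self.rng.standard_normal()
            theta_j = np.exp(-(self.delta * self.alpha + prop[j]))
            ll_new_j = _bb_loglik(self.a[:, j], self.n[:, j], self.p, theta_j)
            delta_ll = ll_new_j.sum() - self.ll[:, j].sum()
            log_prior = 0.5 * ((self.beta[j] + 1.0) ** 2 - (prop[j] + 1.0) ** 2)
            if np.log(self.rng.random()) < delta_ll + log_prior:
                self.beta = prop
                self.ll[:, j] = ll_new_j
                if track is not None:
                    track["beta"][j] += 1

    def sweep(self, track=None):
        self.update_p(track)
        self.update_alpha(track)
        self.update_delta()
        self.update_beta(track)

    def log_posterior(self) -> float:
        lp = float(self.ll.sum())
        lp += float(-0.5 * (self.alpha[self.delta] ** 2).sum())
        lp += float(-0.5 * ((self.beta + 1.0) ** 2).sum())
        lp -= float(self.delta.sum()) * self.log_po  # prior odds on inclusion
        return lp

    # -- pilot tuning --------------------------------------------------------
    def pilot_tune(self):
        cfg = self.cfg
        for _ in range(cfg.n_pilot):
            track = {
                "p": np.zeros(self.L),
                "alpha": np.zeros(self.L),
                "alpha_n": np.zeros(self.L),
                "beta": np.zeros(self.J),
            }
            for _ in range(cfg.pilot_length):
                self.sweep(track)
            rate_p = track["p"] / cfg.pilot_length
            self.w_p = _retune(self.w_p, rate_p)
            with np.errstate(invalid="ignore", divide="ignore"):
                rate_a = np.where(track["alpha_n"] > 0,
                                  track["alpha"] / np.maximum(track["alpha_n"], 1), np.nan)
            self.w_a = np.where(np.isfinite(rate_a), _retune(self.w_a, rate_a), self.w_a)
            self.w_b = _retune(self.w_b, track["beta"] / cfg.pilot_length)


def _retune(width, rate, lo=0.25, hi=0.45, factor=1.25):
    width = np.where(rate > hi, width * factor, width)
    width = np.where(rate < lo, width / factor, width)
    return np.clip(width, 1e-4, 10.0)


def bayescan_fit(
    gm: GenotypeMatrix,
    groups: list[str] | None = None,
    cfg: MCMCConfig | None = None,
) -> OutlierResult:
    """Fit the Bayesian logistic-FST outlier model to a two-group matrix.

    Requires a filtered matrix: every locus must be polymorphic and have at
    least one called genotype in each group.  Returns per-locus posterior
    inclusion probabilities, conditional effect-size means, per-group FST
    posterior means and q-values.
    """
    cfg = cfg or MCMCConfig()
    cfg.validate()
    levels = groups if groups is not None else gm.group_levels
    if len(levels) != 2:
        raise ValueError("bayescan_fit is exercised for exactly two groups")
    a, n, _ = gm.allele_counts(levels)
    if (n == 0).any():
        bad = [gm.locus_ids[i] for i in np.where((n == 0).any(axis=1))[0][:5]]
        raise ValueError(
            f"every locus needs called genotypes in both groups; offenders: {bad}"
        )
    pooled = a.sum(axis=1) / n.sum(axis=1)
    if ((pooled == 0) | (pooled == 1)).any():
        raise ValueError("monomorphic loci present; filter the matrix first")

    rng = np.random.default_rng(cfg.seed)
    state = _BayescanState(a, n, cfg, rng)
    state.pilot_tune()
    for _ in range(cfg.burn_in):
        state.sweep()

    L = state.L
    sum_delta = np.zeros(L)
    sum_alpha = np.zeros(L)
    n_alpha = np.zeros(L)
    sum_fst = np.zeros((L, 2))
    sum_beta = np.zeros(2)
    diag_rows = []
    for it in range(cfg.n_output):
        for _ in range(cfg.thinning):
            state.sweep()
        sum_delta += state.delta
        sum_alpha += np.where(state.delta, state.alpha, 0.0)
        n_alpha += state.delta
        x = state.delta[:, None] * state.alpha[:, None] + state.beta[None, :]
        sum_fst += expit(x)
        sum_beta += state.beta
        diag_rows.append((it, state.log_posterior(), int(state.delta.sum())))

    post_p = sum_delta / cfg.n_output
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mean = np.where(n_alpha > 0, sum_alpha / np.maximum(n_alpha, 1), 0.0)
    fst_mean = sum_fst / cfg.n_output
    q = qvalues_from_posteriors(post_p)

    table = pd.DataFrame(
        {
            "posterior_prob": post_p,
            "alpha_mean": alpha_mean,
            "fst_g1": fst_mean[:, 0],
            "fst_g2": fst_mean[:, 1],
            "q_value": q,
        },
        index=pd.Index(gm.locus_ids, name="locus_id"),
    )
    diagnostics = pd.DataFrame(
        diag_rows, columns=["iteration", "log_posterior", "n_included"]
    )
    return OutlierResult(
        table=table,
        beta_mean=sum_beta / cfg.n_output,
        group_levels=list(levels),
        diagnostics=diagnostics,
    )


def qvalues_from_posteriors(post_p: np.ndarray) -> np.ndarray:
    """q-value per locus from posterior inclusion probabilities.

    ``q_i`` is the mean of ``1 − P_j`` over all loci with ``P_j ≥ P_i`` —
    the expected false-discovery rate of the outlier list thresholded at
    locus *i*.  Sorting loci by decreasing P yields nondecreasing q.
    """
    p = np.asarray(post_p, dtype=float)
    if p.size == 0:
        raise ValueError("empty posterior-probability vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("posterior probabilities must lie in [0, 1]")
    order = np.argsort(-p, kind="stable")
    sorted_p = p[order]
    running = np.cumsum(1.0 - sorted_p) / np.arange(1, p.size + 1)
    # ties must share the q of the last tied element
    q_sorted = running.copy()
    i = p.size - 1
    while i > 0:
        if sorted_p[i - 1] == sorted_p[i]:
            q_sorted[i - 1] = q_sorted[i]
        i -= 1
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# PCA-based scan
# ---------------------------------------------------------------------------


def pcadapt_scan(gm: GenotypeMatrix, K: int, seed: int = 0) -> pd.DataFrame:
    """PCA-regression genome scan with robust Mahalanobis distances.

    Each standardized SNP is regressed on the leading ``K`` PC score
    vectors; the per-SNP z-statistics are combined into a robust Mahalanobis
    distance (minimum-covariance-determinant, support fraction 0.75),
    rescaled by the genomic inflation factor λ and referred to a χ²(K)
    distribution; q-values are Benjamini–Hochberg.

    Returns a DataFrame indexed by locus with columns ``stat`` (D²),
    ``p_value`` and ``q_value``; loci excluded as monomorphic carry NaN.
    """
    from .structure import pca as _pca  # local import avoids a cycle

    if K < 1:
        raise ValueError("K must be at least 1")
    if K >= gm.n_individuals:
        raise ValueError("K must be smaller than the number of individuals")
    res = _pca(gm, k_max=K)
    scores = res.scores  # (n, K), orthogonal columns
    nind = gm.n_individuals

    # standardized matrix restricted to the loci the PCA used
    sub = gm.subset_loci(res.loci_used)
    p = sub.alt_freq()
    called = sub.called_mask()
    x = np.where(called, sub.calls - 2.0 * p, 0.0) / np.sqrt(2.0 * p * (1.0 - p))

    design = np.column_stack([np.ones(nind), scores])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef
    dof = max(nind - K - 1, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.outer(np.diag(xtx_inv)[1:], sigma2))  # (K, L)
    z = (coef[1:] / se).T  # (L, K)

    mcd = MinCovDet(support_fraction=0.75, random_state=seed).fit(z)
    d2 = mcd.mahalanobis(z)
    lam = np.median(d2) / stats.chi2.ppf(0.5, df=K)
    pvals = stats.chi2.sf(d2 / lam, df=K)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    out = pd.DataFrame(
        {"stat": d2, "p_value": pvals, "q_value": qvals},
        index=pd.Index(res.loci_used, name="locus_id"),
    )
    out.attrs["lambda"] = float(lam)
    out.attrs["K"] = K
    # reindex to the full locus set; excluded loci get NaN
    return out.reindex(gm.locus_ids)
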