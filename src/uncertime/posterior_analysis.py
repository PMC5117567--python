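"""Propagation of pseudotime posterior uncertainty into downstream analyses.

A point pseudotime estimate hides the fact that many orderings are nearly
equally consistent with the data.  Here the switch-model differential
expression test is re-run on every retained posterior pseudotime draw, and
genes are classified as

* robust        — significant (q < alpha) at the MAP pseudotime AND in at
                  least tau (default 95%) of posterior draws,
* unstable      — significant at the MAP but in fewer than tau of draws,
* not_significant otherwise.

The same per-draw refits give posterior distributions over each gene's
activation strength k and activation time t0, pairwise ordering
probabilities ("in what fraction of draws does gene a switch before gene
b?"), and the module also hosts the point-estimate baseline (diameter path
of the Euclidean minimum spanning tree) and the subsampling stability
experiments that contrast it with the probabilistic estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree, shortest_path
from scipy.spatial.distance import squareform, pdist

from .embed import Embedding, ExpressionMatrix, pca_embed, select_genes, standardize
from .gplvm import (
    GPLVMHyperparams,
    MCMCSettings,
    PseudotimePosterior,
    hpd_interval,
    orient_and_map,
    sample_posterior,
)
from .switchde import de_test_all, fit_models

__all__ = [
    "RobustnessRecord",
    "ActivationPosterior",
    "de_across_samples",
    "classify_robustness",
    "robustness_analysis",
    "activation_posterior",
    "ordering_probability",
    "mst_pseudotime",
    "subsample_stability",
    "StabilityResult",
]

DEFAULT_DRAW_CAP = 100


@dataclass(frozen=True)
class RobustnessRecord:
    gene: str
    q_map: float
    frac_significant: float
    category: str


@dataclass(frozen=True)
class ActivationPosterior:
    """Posterior (over pseudotime draws) of one gene's switch parameters."""

    gene: str
    k_samples: np.ndarray
    t0_samples: np.ndarray
    k_median: float
    k_ci: tuple[float, float]
    t0_median: float
    t0_ci: tuple[float, float]
    n_converged: int


def _thin_draw_indices(n_draws: int, cap: int) -> np.ndarray:
    if n_draws <= cap:
        return np.arange(n_draws)
    return np.unique(np.linspace(0, n_draws - 1, cap).astype(int))


def de_across_samples(
    E: ExpressionMatrix,
    post: PseudotimePosterior,
    min_detect_frac: float = 0.1,
    max_draws: int = DEFAULT_DRAW_CAP,
    n_refine: int | None = None,
) -> pd.DataFrame:
    """Per-gene, per-draw q-value matrix from refitting the switch test on
    each retained posterior pseudotime draw.

    BH correction is applied within each draw.  Draws are thinned evenly to
    at most ``max_draws``.  Returns a DataFrame indexed by gene with one
    column per used draw index.
    """
    kwargs = {} if n_refine is None else {"n_refine": n_refine}
    idx = _thin_draw_indices(post.n_draws, max_draws)
    cols = {}
    for s in idx:
        table = de_test_all(E, post.t[s], min_detect_frac=min_detect_frac, **kwargs)
        cols[int(s)] = table.set_index("gene")["q_value"]
    qmat = pd.DataFrame(cols)
    qmat.index.name = "gene"
    return qmat


def classify_robustness(
    q_map: float, frac_significant: float, alpha: float = 0.05, tau: float = 0.95
) -> str:
    """Classify one gene: ``robust`` iff q_map < alpha and frac_significant
    >= tau; ``unstable`` iff q_map < alpha but frac_significant < tau;
    otherwise ``not_significant``."""
    for name, v in (("q_map", q_map), ("frac_significant", frac_significant)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if q_map < alpha:
        return "robust" if frac_significant >= tau else "unstable"
    return "not_significant"


def robustness_analysis(
    E: ExpressionMatrix,
    post: PseudotimePosterior,
    alpha: float = 0.05,
    tau: float = 0.95,
    min_detect_frac: float = 0.1,
    max_draws: int = DEFAULT_DRAW_CAP,
    n_refine: int | None = None,
) -> pd.DataFrame:
    """Full robust/unstable classification table.

    q_map comes from the switch test at the MAP pseudotime draw;
    frac_significant is the fraction of posterior draws in which the gene
    attains q < alpha.  Returns columns gene, q_map, frac_significant,
    category.
    """
    kwargs = {} if n_refine is None else {"n_refine": n_refine}
    map_table = de_test_all(
        E, post.t[post.map_index], min_detect_frac=min_detect_frac, **kwargs
    ).set_index("gene")
    qmat = de_across_samples(
        E, post, min_detect_frac=min_detect_frac, max_draws=max_draws, n_refine=n_refine
    )
    frac = (qmat < alpha).mean(axis=1)
    genes = map_table.index
    records = [
        RobustnessRecord(
            gene=g,
            q_map=float(map_table.loc[g, "q_value"]),
            frac_significant=float(frac.loc[g]),
            category=classify_robustness(
                float(map_table.loc[g, "q_value"]), float(frac.loc[g]), alpha, tau
            ),
        )
        for g in genes
    ]
    return pd.DataFrame([r.__dict__ for r in records])


def activation_posterior(
    E: ExpressionMatrix,
    post: PseudotimePosterior,
    genes,
    max_draws: int = DEFAULT_DRAW_CAP,
    ci_mass: float = 0.95,
    n_refine: int | None = None,
) -> list[ActivationPosterior]:
    """Approximate posteriors of activation strength and time for the given
    genes by refitting the alternative model on each pseudotime draw.

    Non-converged per-draw fits are excluded from the summaries (their count
    is reflected in ``n_converged``).  Credible intervals are 95% HPD when
    at least 20 converged fits are available, NaN otherwise.
    """
    kwargs = {} if n_refine is None else {"n_refine": n_refine}
    gene_to_row = {g: i for i, g in enumerate(E.gene_ids)}
    for g in genes:
        if g not in gene_to_row:
            raise KeyError(f"gene {g!r} not present in the expression matrix")
    idx = _thin_draw_indices(post.n_draws, max_draws)
    out = []
    for g in genes:
        y = E.values[gene_to_row[g]]
        ks, t0s, ok = [], [], []
        for s in idx:
            fit = fit_models(y, post.t[s], **kwargs)
            ks.append(fit.k)
            t0s.append(fit.t0)
            ok.append(fit.converged and np.isfinite(fit.t0))
        ks, t0s, ok = np.asarray(ks), np.asarray(t0s), np.asarray(ok, dtype=bool)
        kc, t0c = ks[ok], t0s[ok]
        if len(kc) >= 20:
            k_ci = hpd_interval(kc, ci_mass)
            t0_ci = hpd_interval(t0c, ci_mass)
        else:
            k_ci = (np.nan, np.nan)
            t0_ci = (np.nan, np.nan)
        out.append(
            ActivationPosterior(
                gene=g,
                k_samples=ks,
                t0_samples=t0s,
                k_median=float(np.median(kc)) if len(kc) else np.nan,
                k_ci=k_ci,
                t0_median=float(np.median(t0c)) if len(t0c) else np.nan,
                t0_ci=t0_ci,
                n_converged=int(ok.sum()),
            )
        )
    return out


def ordering_probability(t0_a, t0_b) -> float:
    """Fraction of aligned posterior draws in which gene a's activation time
    precedes gene b's; exact ties count one half."""
    a = np.asarray(t0_a, dtype=float)
    b = np.asarray(t0_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("activation-time sample vectors must be aligned (same length)")
    return float(np.mean((a < b) + 0.5 * (a == b)))


def mst_pseudotime(X) -> np.ndarray:
    """Point-estimate pseudotime from the diameter path of the Euclidean
    minimum spanning tree over cells.

    Cells on the diameter path get their normalized cumulative path
    distance; off-path cells inherit the pseudotime of the path vertex
    through which they attach to the diameter.  Output spans [0, 1]
    exactly; the direction is arbitrary (output and 1 - output are equally
    valid).
    """
    coords = X.coords if isinstance(X, Embedding) else np.asarray(X, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells for an MST pseudotime")
    dist = squareform(pdist(coords))
    mst = minimum_spanning_tree(dist)
    tree = mst.maximum(mst.T)  # undirected

    # diameter by double sweep: farthest node from an arbitrary root, then
    # farthest node from that one
    d0 = shortest_path(tree, method="D", directed=False, indices=0)
    u = int(np.argmax(d0))
    du, pred_u = shortest_path(
        tree, method="D", directed=False, indices=u, return_predecessors=True
    )
    v = int(np.argmax(du))

    path = [v]
    while path[-1] != u:
        path.append(int(pred_u[path[-1]]))
    path = path[::-1]  # from u to v
    path_dist = np.concatenate([[0.0], np.cumsum([dist[path[i], path[i + 1]] for i in range(len(path) - 1)])])
    total = path_dist[-1]
    if total == 0:
        raise ValueError("degenerate MST: all cells coincide")
    t_path = path_dist / total

    t = np.full(n, np.nan)
    for node, tv in zip(path, t_path):
        t[node] = tv
    # attach off-path cells: walk each one's tree path until it meets the diameter
    on_path = set(path)
    for i in range(n):
        if np.isnan(t[i]):
            node = i
            while node not in on_path:
                node = int(pred_u[node])  # tree path toward u hits the diameter
            t[i] = t[node]
    return t


@dataclass
class StabilityResult:
    """Per-cell spread of pseudotime estimates across random subsamples."""

    per_cell: pd.DataFrame  # cell, n_appearances, mean, sd, spread_2sigma
    estimates: pd.DataFrame  # cells x subsamples, NaN where cell absent
    robust_counts: pd.Series | None = None  # pipeline estimator only


def _gplvm_point_estimate(X: Embedding, mcmc: MCMCSettings, h: GPLVMHyperparams):
    post = sample_posterior(standardize(X), h, mcmc)
    post = orient_and_map(post, X.coords[:, 0])
    return post


def subsample_stability(
    E: ExpressionMatrix,
    estimator: str | "callable" = "mst",
    frac: float = 0.8,
    B: int = 30,
    seed: int = 0,
    n_top_genes: int | None = None,
    mcmc: MCMCSettings | None = None,
    hyperparams: GPLVMHyperparams | None = None,
    alpha: float = 0.05,
    tau: float = 0.95,
    min_detect_frac: float = 0.1,
    max_draws: int = 20,
    n_refine: int | None = None,
) -> StabilityResult:
    """Refit pseudotime on B random subsamples of ``frac`` of the cells and
    record the per-cell spread of the estimates.

    ``estimator`` is one of

    * ``"mst"``      — PCA then the minimum-spanning-tree diameter baseline,
    * ``"gplvm"``    — PCA then the posterior-mean pseudotime of the GPLVM,
    * ``"pipeline"`` — as "gplvm" plus the robust-DE classification per
      subsample, accumulating for each gene the number of subsamples in
      which it is robust (``robust_counts``),
    * any callable mapping an ExpressionMatrix subset to a pseudotime
      vector.

    Every subsample's estimate is oriented against the full-data first
    principal component so spreads are not inflated by the arbitrary
    direction.  Cells absent from a subsample are recorded as missing.
    """
    if B < 2:
        raise ValueError("need at least B=2 subsamples")
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if mcmc is None:
        mcmc = MCMCSettings(chains=1, warmup=300, samples=300, seed=seed)
    if hyperparams is None:
        hyperparams = GPLVMHyperparams()

    E_sel = select_genes(E, min_detect_frac=min_detect_frac, n_top=n_top_genes)
    ref = pca_embed(E_sel, 2).coords[:, 0]  # orientation reference

    n = E.n_cells
    m = max(3, int(round(frac * n)))
    estimates = np.full((n, B), np.nan)
    robust_counts = None
    if estimator == "pipeline":
        robust_counts = pd.Series(0, index=pd.Index([], name="gene"), dtype=int)

    for b in range(B):
        cells = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        E_sub = ExpressionMatrix(
            E_sel.values[:, cells],
            E_sel.gene_ids,
            tuple(E_sel.cell_ids[i] for i in cells),
        )
        if callable(estimator):
            t_sub = np.asarray(estimator(E_sub), dtype=float)
        elif estimator == "mst":
            t_sub = mst_pseudotime(pca_embed(E_sub, 2))
        elif estimator in ("gplvm", "pipeline"):
            X_sub = pca_embed(E_sub, 2)
            mcmc_b = MCMCSettings(
                chains=mcmc.chains, warmup=mcmc.warmup, samples=mcmc.samples,
                thin=mcmc.thin, seed=(mcmc.seed * 1009 + b) % (2**31 - 1),
                method=mcmc.method, init=mcmc.init, target_accept=mcmc.target_accept,
            )
            post = sample_posterior(standardize(X_sub), hyperparams, mcmc_b)
            post = orient_and_map(post, ref[cells])
            t_sub = post.t_mean()
            if estimator == "pipeline":
                rob = robustness_analysis(
                    E_sub, post, alpha=alpha, tau=tau,
                    min_detect_frac=min_detect_frac, max_draws=max_draws,
                    n_refine=n_refine,
                ).set_index("gene")
                robust_genes = rob.index[rob["category"] == "robust"]
                robust_counts = robust_counts.reindex(
                    robust_counts.index.union(rob.index), fill_value=0
                )
                robust_counts.loc[robust_genes] += 1
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        # orient against the full-data reference
        r = np.asarray(ref[cells], dtype=float)
        if np.ptp(r) > 0 and np.corrcoef(t_sub, r)[0, 1] < 0:
            t_sub = t_sub.max() + t_sub.min() - t_sub
        estimates[cells, b] = t_sub

    est = pd.DataFrame(estimates, index=pd.Index(E.cell_ids, name="cell"))
    with np.errstate(invalid="ignore"):
        per_cell = pd.DataFrame(
            {
                "cell": E.cell_ids,
                "n_appearances": np.sum(~np.isnan(estimates), axis=1),
                "mean": np.nanmean(estimates, axis=1),
                "sd": np.nanstd(estimates, axis=1),
            }
        )
    per_cell["spread_2sigma"] = 2.0 * per_cell["sd"]
    return StabilityResult(per_cell=per_cell, estimates=est, robust_counts=robust_counts)
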