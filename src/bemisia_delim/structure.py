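"""Nuclear-marker population structure.

Operations on an individuals x biallelic-loci alternate-allele dosage
matrix:

* Weir & Cockerham (1984) variance-component Fst (theta), per locus and as
  the multilocus ratio of sums, and a pairwise population matrix;
* genotype PCA with Patterson frequency scaling;
* model-based ancestry: the ADMIXTURE/STRUCTURE binomial mixture
  likelihood maximised by EM over Q (individual ancestry proportions) and
  P (cluster allele frequencies), with random restarts;
* held-out cross-validation over K (masked-entry prediction error);
* a neighbor-joining tree on allele-sharing distances, for qualitative
  cluster context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .sim import MISSING

P_EPS = 1e-6  # cluster allele frequencies clamped to [P_EPS, 1 - P_EPS]


@dataclass
class GenotypeMatrix:
    """Individuals x loci alternate-allele dosages; ``MISSING`` (-1) = no call."""

    dosages: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, l = self.dosages.shape
        if n != len(self.individual_ids) or l != len(self.locus_ids):
            raise ValueError("dosage matrix shape does not match id lists")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        valid = self.dosages != MISSING
        if np.any((self.dosages > self.ploidy) & valid) or np.any(self.dosages < MISSING):
            raise ValueError("dosages must be in {0..ploidy} or MISSING")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.individual_ids.index(i) for i in ids]
        return GenotypeMatrix(
            self.dosages[idx], list(ids), list(self.locus_ids), self.ploidy
        )


@dataclass
class PopulationMap:
    """Individual id -> population label; preserves first-seen label order."""

    population_of: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.population_of.values():
            if p not in seen:
                seen.append(p)
        return seen

    def members(self, pop: str) -> list[str]:
        return [i for i, p in self.population_of.items() if p == pop]

    def check_covers(self, matrix: GenotypeMatrix) -> None:
        missing = [i for i in matrix.individual_ids if i not in self.population_of]
        if missing:
            raise ValueError(f"individuals missing from population map: {missing[:5]}")


@dataclass
class FstResult:
    a: np.ndarray  # per-locus among-population component
    b: np.ndarray  # among individuals within populations
    c: np.ndarray  # within individuals
    theta: np.ndarray  # per-locus a/(a+b+c); NaN where undefined
    theta_multilocus: float
    populations: list[str]
    n_loci_used: int


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # all, non-increasing
    coordinates: np.ndarray  # individuals x n_components
    variance_explained: np.ndarray  # per reported component
    n_loci_used: int
    individual_ids: list[str]


@dataclass
class AncestryModel:
    K: int
    Q: np.ndarray  # individuals x K
    P: np.ndarray  # K x loci
    log_likelihood: list[float]  # trace of the best restart
    seed: int
    n_restarts: int
    converged: bool
    individual_ids: list[str] = field(default_factory=list)


@dataclass
class CvReport:
    k_values: list[int]
    mean_error: list[float]
    sd_error: list[float]
    chosen_k: int


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984)


def wc_fst_locus(pop_dosages: list[np.ndarray], ploidy: int = 2):
    """Variance components (a, b, c) and theta for one biallelic locus.

    ``pop_dosages`` holds, per population, the non-missing dosage vector.
    Diploid data uses the full three-component estimator with the observed
    heterozygote proportion; haploid data the two-level estimator (c = 0).
    A locus monomorphic across all populations has all components zero and
    theta undefined (NaN).
    """
    counts = [np.asarray(d, dtype=float) for d in pop_dosages if len(d) > 0]
    r = len(counts)
    if r < 2:
        raise ValueError("need >= 2 populations with data at the locus")
    n = np.array([len(d) for d in counts], dtype=float)
    p = np.array([d.mean() / ploidy for d in counts])
    nbar = n.mean()
    if nbar <= 1 and ploidy == 2:
        raise ValueError("diploid estimator needs average sample size > 1")
    n_c = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    if pbar in (0.0, 1.0):
        return 0.0, 0.0, 0.0, float("nan")
    if ploidy == 2:
        h = np.array([(d == 1).mean() for d in counts])
        hbar = (n * h).sum() / (r * nbar)
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    else:
        if nbar <= 1:
            raise ValueError("haploid estimator needs average sample size > 1")
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
        c = 0.0
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return float(a), float(b), float(c), float(theta)


def wc_fst(matrix: GenotypeMatrix, popmap: PopulationMap) -> FstResult:
    """Per-locus W&C components across all mapped populations, plus the
    multilocus ratio-of-sums theta = sum(a) / sum(a+b+c) over informative loci."""
    popmap.check_covers(matrix)
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("Fst needs >= 2 populations")
    idx = {p: [matrix.individual_ids.index(i) for i in popmap.members(p)
               if i in matrix.individual_ids] for p in pops}
    L = matrix.n_loci
    a = np.full(L, np.nan)
    b = np.full(L, np.nan)
    c = np.full(L, np.nan)
    theta = np.full(L, np.nan)
    n_skipped = 0
    for l in range(L):
        col = matrix.dosages[:, l]
        per_pop = []
        for p in pops:
            d = col[idx[p]]
            per_pop.append(d[d != MISSING])
        if any(len(d) == 0 for d in per_pop):
            n_skipped += 1
            continue
        a[l], b[l], c[l], theta[l] = wc_fst_locus(per_pop, matrix.ploidy)
    informative = ~np.isnan(theta)
    if not informative.any():
        raise ValueError("no informative loci for Fst")
    tot = (a + b + c)[informative]
    theta_ml = float(a[informative].sum() / tot.sum())
    return FstResult(
        a=a, b=b, c=c, theta=theta,
        theta_multilocus=theta_ml,
        populations=pops,
        n_loci_used=int(informative.sum()),
    )


def wc_fst_multilocus(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Ratio-of-sums multilocus theta over informative (non-NaN) loci."""
    a = np.asarray(a, dtype=float)
    tot = a + np.asarray(b, dtype=float) + np.asarray(c, dtype=float)
    ok = ~np.isnan(tot) & (tot != 0)
    # exclude loci whose theta was undefined (all components zero)
    ok &= ~((a == 0) & (tot == 0))
    if not ok.any():
        raise ValueError("no informative loci")
    return float(a[ok].sum() / tot[ok].sum())


def pairwise_fst_matrix(
    matrix: GenotypeMatrix, popmap: PopulationMap
) -> tuple[np.ndarray, list[str]]:
    """Multilocus theta for every unordered population pair.

    Each pair is computed on that pair's individuals only.  Returns a
    symmetric matrix (NaN diagonal) ordered as the popmap's label order.
    """
    popmap.check_covers(matrix)
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    out = np.full((len(pops), len(pops)), np.nan)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            ids = popmap.members(pops[i]) + popmap.members(pops[j])
            ids = [x for x in ids if x in matrix.individual_ids]
            sub = matrix.subset_individuals(ids)
            subpop = PopulationMap({x: popmap.population_of[x] for x in ids})
            res = wc_fst(sub, subpop)
            out[i, j] = out[j, i] = res.theta_multilocus
    return out, pops


# ---------------------------------------------------------------------------
# PCA


def pca_genotypes(
    matrix: GenotypeMatrix,
    scaling: str = "patterson",
    n_components: int = 10,
    min_call_rate: float = 0.5,
) -> PcaResult:
    """Eigendecomposition of the individual covariance of scaled dosages.

    Loci with call rate below ``min_call_rate`` or zero variance are
    removed; missing dosages are imputed to the locus mean; columns are
    mean-centred and, under Patterson scaling, divided by
    sqrt(p(1-p) * ploidy) where p is the mean allele frequency.
    """
    if matrix.n_individuals < 2:
        raise ValueError("PCA needs >= 2 individuals")
    if scaling not in ("patterson", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    G = matrix.dosages.astype(float)
    G[matrix.dosages == MISSING] = np.nan
    call_rate = 1.0 - np.isnan(G).mean(axis=0)
    keep = call_rate >= min_call_rate
    G = G[:, keep]
    mu = np.nanmean(G, axis=0)
    var = np.nanvar(G, axis=0)
    poly = var > 0
    G = G[:, poly]
    mu = mu[poly]
    if G.shape[1] == 0:
        raise ValueError("all loci filtered out")
    inds = np.where(np.isnan(G))
    G[inds] = mu[inds[1]]
    X = G - mu
    if scaling == "patterson":
        p = mu / matrix.ploidy
        X = X / np.sqrt(p * (1 - p) * matrix.ploidy)
    L = X.shape[1]
    cov = X @ X.T / L
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    k = min(n_components, len(evals))
    coords = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0, None))
    total = np.clip(evals, 0, None).sum()
    return PcaResult(
        eigenvalues=evals,
        coordinates=coords,
        variance_explained=np.clip(evals[:k], 0, None) / total,
        n_loci_used=L,
        individual_ids=list(matrix.individual_ids),
    )


# ---------------------------------------------------------------------------
# ancestry EM


def _em_fit(G, valid, ploidy, K, rng, tol, max_iter):
    """One EM run from a random start; returns (Q, P, trace, converged)."""
    N, L = G.shape
    n_valid = valid.sum(axis=1)
    if np.any(n_valid == 0):
        raise ValueError("individual with no called genotypes")
    g = np.where(valid, G, 0).astype(float)
    obs_freq = g.sum(axis=0) / (ploidy * valid.sum(axis=0).clip(min=1))
    Q = rng.dirichlet(np.ones(K), size=N)
    P = np.clip(
        obs_freq + rng.uniform(-0.1, 0.1, size=(K, L)), P_EPS, 1 - P_EPS
    )
    trace: list[float] = []
    converged = False
    prev = -np.inf
    for _ in range(max_iter):
        A = np.clip(Q @ P, 1e-12, 1 - 1e-12)
        B = 1.0 - A
        ll = float(np.sum(np.where(valid, g * np.log(A) + (ploidy - g) * np.log(B), 0.0)))
        trace.append(ll)
        if ll - prev < tol * (abs(prev) + 1.0) and len(trace) > 1:
            converged = True
            break
        prev = ll
        Xa = np.where(valid, g / A, 0.0)
        Xr = np.where(valid, (ploidy - g) / B, 0.0)
        Qn = Q * (Xa @ P.T + Xr @ (1.0 - P).T)
        Ea = P * (Q.T @ Xa)
        Er = (1.0 - P) * (Q.T @ Xr)
        Q = Qn / (ploidy * n_valid)[:, None]
        Q = np.clip(Q, 0.0, None)
        Q /= Q.sum(axis=1, keepdims=True)
        P = np.clip(Ea / np.clip(Ea + Er, 1e-300, None), P_EPS, 1 - P_EPS)
    return Q, P, trace, converged


def admixture_em(
    matrix: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 10,
) -> AncestryModel:
    """Maximum-likelihood Q and P under the binomial admixture model.

    The log-likelihood sum_i sum_l [g log(q_i' p_l) + (ploidy - g)
    log(q_i' (1-p_l))] is maximised by EM; ``n_restarts`` random starts are
    run from sub-seeds of ``seed`` and the best-likelihood fit returned.
    Cluster allele frequencies are clamped away from {0,1} to avoid log(0).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    valid = matrix.dosages != MISSING
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        sub = np.random.default_rng(rng.integers(0, 2**31))
        Q, P, trace, conv = _em_fit(
            matrix.dosages, valid, matrix.ploidy, K, sub, tol, max_iter
        )
        if best is None or trace[-1] > best[2][-1]:
            best = (Q, P, trace, conv)
    Q, P, trace, conv = best
    return AncestryModel(
        K=K, Q=Q, P=P, log_likelihood=trace, seed=seed,
        n_restarts=n_restarts, converged=conv,
        individual_ids=list(matrix.individual_ids),
    )


def align_q_columns(Q_est: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute estimated ancestry columns to best match the truth.

    EM solutions are identified only up to cluster relabelling; the
    Hungarian algorithm finds the column permutation minimising total
    absolute difference.
    """
    K = Q_true.shape[1]
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = np.abs(Q_est[:, i] - Q_true[:, j]).sum()
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return Q_est[:, perm]


def choose_k_cv(
    matrix: GenotypeMatrix,
    k_values: list[int],
    mask_fraction: float = 0.1,
    n_folds: int = 5,
    seed: int = 0,
    n_restarts: int = 2,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> CvReport:
    """Choose K by held-out genotype prediction.

    Per fold, ``mask_fraction`` of non-missing entries is masked, the model
    refitted on the remainder, and the error is the mean squared difference
    between each masked dosage and its expectation ploidy * q_i' p_l.
    Chosen K minimises the mean error across folds; ties go to smaller K.
    """
    if not 0.0 < mask_fraction < 1.0:
        raise ValueError("mask_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    valid_idx = np.argwhere(matrix.dosages != MISSING)
    n_mask = max(1, int(round(mask_fraction * len(valid_idx))))
    folds = []
    for _ in range(n_folds):
        pick = rng.choice(len(valid_idx), size=n_mask, replace=False)
        folds.append(valid_idx[pick])
    mean_err, sd_err = [], []
    for K in k_values:
        errs = []
        for fold in folds:
            masked = matrix.dosages.copy()
            masked[fold[:, 0], fold[:, 1]] = MISSING
            sub = GenotypeMatrix(
                masked, matrix.individual_ids, matrix.locus_ids, matrix.ploidy
            )
            model = admixture_em(
                sub, K, seed=int(rng.integers(0, 2**31)),
                tol=tol, max_iter=max_iter, n_restarts=n_restarts,
            )
            expected = matrix.ploidy * (model.Q @ model.P)
            truth = matrix.dosages[fold[:, 0], fold[:, 1]]
            pred = expected[fold[:, 0], fold[:, 1]]
            errs.append(float(np.mean((truth - pred) ** 2)))
        mean_err.append(float(np.mean(errs)))
        sd_err.append(float(np.std(errs)))
    best = int(np.argmin(mean_err))
    # ties (within float equality) go to the smaller K
    for i in range(best):
        if mean_err[i] == mean_err[best]:
            best = i
            break
    return CvReport(
        k_values=list(k_values), mean_error=mean_err, sd_error=sd_err,
        chosen_k=int(k_values[best]),
    )


# ---------------------------------------------------------------------------
# neighbor joining


def allele_sharing_distance(
    matrix: GenotypeMatrix, popmap: PopulationMap | None = None
) -> tuple[np.ndarray, list[str]]:
    """Missing-aware allele-sharing distance.

    Between individuals: mean over co-called loci of |g_i - g_j| / ploidy.
    With a population map, population mean dosages are compared instead.
    """
    if popmap is None:
        profiles = matrix.dosages.astype(float)
        profiles[matrix.dosages == MISSING] = np.nan
        labels = list(matrix.individual_ids)
    else:
        popmap.check_covers(matrix)
        labels = popmap.populations
        rows = []
        for p in labels:
            idx = [matrix.individual_ids.index(i) for i in popmap.members(p)]
            block = matrix.dosages[idx].astype(float)
            block[matrix.dosages[idx] == MISSING] = np.nan
            rows.append(np.nanmean(block, axis=0))
        profiles = np.vstack(rows)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(profiles[i] - profiles[j])
            ok = ~np.isnan(diff)
            if not ok.any():
                raise ValueError(
                    f"no co-called loci between {labels[i]!r} and {labels[j]!r}"
                )
            D[i, j] = D[j, i] = float(diff[ok].mean() / matrix.ploidy)
    return D, labels


def nj_tree(matrix: GenotypeMatrix, popmap: PopulationMap | None = None) -> str:
    """Saitou–Nei neighbor-joining newick tree on allele-sharing distances."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D, labels = allele_sharing_distance(matrix, popmap)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    tree = nj(DistanceMatrix(D, ids=labels))
    return str(tree).strip()
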