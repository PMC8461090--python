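"""Alpha diversity, beta diversity, ordination and PERMANOVA.

Alpha indices are computed per sample from raw counts. Beta diversity is
taxonomic (Bray-Curtis) or phylogenetic (unweighted UniFrac); both return a
``skbio.DistanceMatrix``. Ordination is classical PCoA or nonmetric MDS
(Kruskal stress-1 minimised by SMACOF with isotonic regression). Group
differences are tested with one-way PERMANOVA (the ADONIS pseudo-F with a
permutation p-value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.manifold import smacof

from .community import CommunityTable, ValidationError, relative_abundance

# -- alpha diversity -------------------------------------------------------


def observed_richness(counts) -> int:
    """Number of taxa with nonzero count."""
    return int(np.count_nonzero(np.asarray(counts)))


def shannon(counts) -> float:
    """Shannon entropy −Σ p ln p in nats."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon undefined for a zero-total sample")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Gini-Simpson index 1 − Σ p²."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Simpson undefined for a zero-total sample")
    p = c / total
    return float(1.0 - (p ** 2).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1−1)/(2(F2+1))."""
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("Chao1 requires integer counts")
        c = np.round(c).astype(np.int64)
    s_obs = np.count_nonzero(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def alpha_diversity_table(table: CommunityTable) -> pd.DataFrame:
    """All four alpha indices for every sample, as a tidy DataFrame."""
    rows = []
    for sid, row in zip(table.sample_ids, table.counts):
        rows.append(
            {
                "sample_id": sid,
                "observed": observed_richness(row),
                "shannon": shannon(row),
                "simpson": simpson(row),
                "chao1": chao1(row),
            }
        )
    return pd.DataFrame(rows)


# -- beta diversity --------------------------------------------------------


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d = 1 − 2·Σmin/(Σx+Σy)."""
    sums = table.sample_sums()
    if (sums == 0).any():
        bad = table.sample_ids[int(np.flatnonzero(sums == 0)[0])]
        raise ValidationError(f"zero-sum sample {bad!r}")
    if len(set(sums.tolist())) > 1:
        warnings.warn(
            "Bray-Curtis on unequal sample depths; rarefy first for "
            "effort-independent comparisons",
            stacklevel=2,
        )
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def unweighted_unifrac(table: CommunityTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unique branch length / total branch length of the
    union, with branches attributed by descendant-tip presence."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(table.taxon_ids) - tips)
    if missing:
        raise ValidationError(f"taxa missing from tree: {missing[:10]}")
    return beta_diversity(
        "unweighted_unifrac",
        table.counts,
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
    )


# -- ordination ------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Sample coordinates from PCoA or NMDS.

    ``values`` holds eigenvalues (PCoA) or the final stress-1 (NMDS, a
    single number). ``converged`` is NMDS-only.
    """

    method: str
    coordinates: pd.DataFrame
    values: np.ndarray
    converged: bool = True


def pcoa(d: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Axes are ordered by decreasing eigenvalue; axes with non-positive
    eigenvalues carry no metric information and are dropped (with a warning
    if that truncates below ``k``).
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        res = _skbio_pcoa(d, method="eigh")
    eig = res.eigvals.to_numpy()
    n_pos = int((eig > 1e-12).sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive-eigenvalue axes available; truncating from k={k}",
            stacklevel=2,
        )
    k_eff = max(min(k, n_pos), 0)
    coords = res.samples.iloc[:, :k_eff]
    coords.columns = [f"PC{i + 1}" for i in range(k_eff)]
    coords.index = list(d.ids)
    return OrdinationResult(method="pcoa", coordinates=coords, values=eig)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
    n_starts: int = 20,
) -> OrdinationResult:
    """Nonmetric MDS minimising Kruskal stress-1.

    Runs SMACOF with isotonic regression on the ranked dissimilarities,
    best of ``n_starts`` restarts; the first start is the PCoA configuration
    and the rest are random. Returns the configuration with lowest stress.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    dmat = d.data
    n = dmat.shape[0]
    if np.allclose(dmat, 0):
        coords = pd.DataFrame(
            np.zeros((n, k)), index=list(d.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
        )
        return OrdinationResult("nmds", coords, np.array([0.0]), True)
    rng = np.random.default_rng(seed)
    inits: list[np.ndarray | None] = []
    pco = pcoa(d, k=k).coordinates.to_numpy()
    if pco.shape[1] < k:  # pad degenerate PCoA with tiny jitter
        pad = rng.normal(scale=1e-6, size=(n, k - pco.shape[1]))
        pco = np.hstack([pco, pad])
    inits.append(pco)
    inits.extend(None for _ in range(max(n_starts - 1, 0)))
    best_pos, best_stress = None, np.inf
    for init in inits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pos, stress = smacof(
                dmat,
                metric=False,
                n_components=k,
                init=init,
                n_init=1,
                max_iter=max_iter,
                eps=tol,
                random_state=int(rng.integers(2**31)),
                normalized_stress=True,
            )
        if stress < best_stress:
            best_pos, best_stress = pos, stress
    coords = pd.DataFrame(
        best_pos, index=list(d.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult("nmds", coords, np.array([best_stress]), True)


# -- PERMANOVA -------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Total and within-group sums of squared distances (Anderson partition)."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA (ADONIS) of a distance matrix against a factor.

    The pseudo-F statistic partitions squared inter-point distances:
    F = (SS_between/(g−1)) / (SS_within/(n−g)). The p-value is
    (1 + #{permuted F ≥ observed}) / (1 + n_perm), so it can never be 0.
    """
    labels_raw = np.asarray(list(groups))
    n = d.shape[0]
    if labels_raw.shape[0] != n:
        raise ValueError("grouping length does not match distance matrix")
    _, labels = np.unique(labels_raw, return_inverse=True)
    g = labels.max() + 1
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    d2 = d.data.astype(float) ** 2

    def f_stat(lab: np.ndarray) -> float:
        ss_total, ss_within = _permanova_ss(d2, lab, g)
        ss_between = ss_total - ss_within
        denom = ss_within / (n - g)
        if denom == 0:
            return np.inf
        return (ss_between / (g - 1)) / denom

    ss_total, ss_within = _permanova_ss(d2, labels, g)
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    f_obs = f_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if f_stat(perm) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(r2),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
    )
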