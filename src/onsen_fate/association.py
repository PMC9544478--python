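"""Association between gene-local SNP variation and climatic aridity.

Re-creates, for a small SNP panel, the natural-accession analysis stage:
read biallelic SNP genotypes into a dosage matrix, keep common SNPs
(minor allele frequency strictly above 0.3), collapse duplicated or
clonal ecotypes by KING-robust kinship (drop pairs with k >= 0.5), then
test each SNP against an aridity phenotype (Global Aridity Index averaged
over summer months) with a linear mixed model that uses the admixture
group of each ecotype as a single random effect to absorb population
structure:

    aridity_i = mu + beta * dosage_i + u_group(i) + e_i,
    u_g ~ N(0, sigma_g^2),  e_i ~ N(0, sigma_e^2).

The model is fitted by maximum likelihood: the variance ratio
lambda = sigma_g^2 / sigma_e^2 is profiled on a 1-D grid search with
generalized-least-squares fixed effects at each ratio (the group-block
covariance inverts in closed form).  Variance explained by the SNP is
reported as the fixed-effect share of the total modelled variance,
100 * beta^2 Var(dosage) / (beta^2 Var(dosage) + sigma_g^2 + sigma_e^2).
Linkage disequilibrium among panel SNPs is the squared Pearson
correlation of dosage vectors (composite LD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GenotypePanel",
    "LmmFit",
    "read_genotypes",
    "maf_filter",
    "king_kinship",
    "prune_related",
    "fit_lmm_snp",
    "ld_r2",
]


@dataclass
class GenotypePanel:
    """Ecotype-by-SNP dosage matrix with group labels and aridity values.

    ``dosages`` counts alternate alleles (0/1/2; NaN for missing) and has
    shape (n_ecotypes, n_snps).
    """

    ecotypes: list[str]
    snp_ids: list[str]
    positions: list[int]
    dosages: np.ndarray
    groups: np.ndarray | None = None
    aridity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ecotypes), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match ids")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]

    def subset_ecotypes(self, keep: list[str]) -> "GenotypePanel":
        idx = [self.ecotypes.index(e) for e in keep]
        return GenotypePanel(
            ecotypes=list(keep),
            snp_ids=list(self.snp_ids),
            positions=list(self.positions),
            dosages=self.dosages[idx],
            groups=None if self.groups is None else np.asarray(self.groups)[idx],
            aridity=None if self.aridity is None else np.asarray(self.aridity)[idx],
        )


@dataclass
class LmmFit:
    """Maximum-likelihood fit of the one-random-effect aridity model."""

    snp_id: str
    intercept: float
    beta: float
    beta_se: float
    p_value: float
    sigma2_group: float
    sigma2_resid: float
    variance_explained: float  # percent
    log_likelihood: float
    n: int


def read_genotypes(
    vcf_path: str | Path,
    groups: pd.Series | None = None,
    aridity: pd.Series | None = None,
) -> GenotypePanel:
    """Load a GT-only VCF subset into a dosage panel.

    Dosage is the alternate-allele count per diploid genotype; half-missing
    or fully missing calls become NaN.  Multiallelic records are skipped
    with a warning.  ``groups``/``aridity`` are optional per-ecotype Series
    indexed by sample id and are aligned to the VCF sample order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{vcf_path}: no samples (GT columns) in VCF")
    snp_ids: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            warnings.warn(
                f"skipping multiallelic site {variant.CHROM}:{variant.POS}",
                stacklevel=2,
            )
            continue
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            if len(alleles) < 2 or any(a < 0 for a in alleles):
                continue
            col[i] = float(sum(1 for a in alleles if a > 0))
        vid = variant.ID or f"{variant.CHROM}_{variant.POS}"
        snp_ids.append(vid)
        positions.append(int(variant.POS))
        columns.append(col)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    grp = None if groups is None else groups.reindex(samples).to_numpy()
    ari = None if aridity is None else aridity.reindex(samples).to_numpy(dtype=float)
    return GenotypePanel(samples, snp_ids, positions, dosages, grp, ari)


def maf_filter(panel: GenotypePanel, threshold: float = 0.3) -> list[str]:
    """SNP ids whose minor allele frequency is strictly above ``threshold``.

    Frequencies are computed over non-missing alleles; all-missing SNPs
    are dropped with a warning.
    """
    keep = []
    for j, snp in enumerate(panel.snp_ids):
        d = panel.dosages[:, j]
        ok = ~np.isnan(d)
        if not ok.any():
            warnings.warn(f"SNP {snp}: all genotypes missing; dropped", stacklevel=2)
            continue
        p = d[ok].sum() / (2.0 * ok.sum())
        if min(p, 1.0 - p) > threshold:
            keep.append(snp)
    return keep


def king_kinship(panel: GenotypePanel) -> pd.DataFrame:
    """Pairwise KING-robust kinship coefficients.

    For ecotypes i, j over their shared non-missing sites:

        k_ij = (N_het,het − 2 N_opposing_hom) / (N_het,i + N_het,j)

    where N_het,i counts i's heterozygous genotypes among shared sites.
    Duplicate individuals give k = 0.5 whenever they carry at least one
    heterozygous site; pairs with no heterozygous site in either member
    are undefined (NaN).  The diagonal is set to 0.5 by convention.
    """
    if len(panel.ecotypes) < 2:
        raise ValueError("need at least two ecotypes")
    d = panel.dosages
    present = (~np.isnan(d)).astype(float)
    het = (d == 1.0).astype(float)
    hom0 = (d == 0.0).astype(float)
    hom2 = (d == 2.0).astype(float)
    n_hh = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    # heterozygous sites of i restricted to sites shared with j
    n_het_i = het @ present.T
    denom = n_het_i + n_het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(denom > 0, (n_hh - 2.0 * n_opp) / denom, np.nan)
    np.fill_diagonal(k, 0.5)
    return pd.DataFrame(k, index=panel.ecotypes, columns=panel.ecotypes)


def prune_related(
    panel: GenotypePanel, kinship: pd.DataFrame, cutoff: float = 0.5
) -> list[str]:
    """Greedy pruning to a set of ecotypes with all pairwise k < cutoff.

    While any off-diagonal kinship is at or above the cutoff, the ecotype
    involved in the largest number of such pairs is dropped (ties broken
    by dropping the lexicographically smallest id), so each cluster of
    duplicates keeps exactly one representative.
    """
    k = kinship.to_numpy(copy=True)
    np.fill_diagonal(k, np.nan)
    ids = list(kinship.index)
    active = set(range(len(ids)))
    while True:
        over = {}
        for i in sorted(active):
            row = [j for j in active if j != i and not np.isnan(k[i, j]) and k[i, j] >= cutoff]
            if row:
                over[i] = len(row)
        if not over:
            break
        worst = max(over.values())
        drop = min((i for i, c in over.items() if c == worst), key=lambda i: ids[i])
        active.remove(drop)
    return [ids[i] for i in sorted(active)]


def _profile_negloglik(
    lam: float,
    x_groups: list[np.ndarray],
    y_groups: list[np.ndarray],
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Negative profile log-likelihood at variance ratio ``lam``.

    Within a group of size m the covariance block is I + lam*J, whose
    inverse is I − (lam/(1+lam*m)) J, so all GLS cross-products reduce to
    per-group sums.  Returns (-loglik, beta_hat, XtVinvX, sigma2_e_hat).
    """
    p = x_groups[0].shape[1]
    a = np.zeros((p, p))
    b = np.zeros(p)
    c = 0.0
    logdet = 0.0
    n = 0
    for xg, yg in zip(x_groups, y_groups):
        m = len(yg)
        n += m
        shrink = lam / (1.0 + lam * m)
        xs = xg.sum(axis=0)
        ys = yg.sum()
        a += xg.T @ xg - shrink * np.outer(xs, xs)
        b += xg.T @ yg - shrink * xs * ys
        c += yg @ yg - shrink * ys * ys
        logdet += np.log1p(lam * m)
    beta = np.linalg.solve(a, b)
    rss = c - beta @ b
    sigma2_e = max(rss / n, 1e-300)
    nll = 0.5 * (n * np.log(2.0 * np.pi * sigma2_e) + logdet + n)
    return nll, beta, a, sigma2_e


def fit_lmm_snp(panel: GenotypePanel, snp_id: str) -> LmmFit:
    """Fit aridity ~ dosage with a group random intercept by ML.

    Ecotypes with a missing dosage, group or aridity value are dropped.
    Requires at least two admixture groups and a non-constant dosage.
    """
    if panel.groups is None or panel.aridity is None:
        raise ValueError("panel needs groups and aridity for association")
    g = panel.dosage(snp_id)
    ok = ~np.isnan(g) & ~pd.isna(panel.groups) & ~np.isnan(panel.aridity)
    g = g[ok]
    y = panel.aridity[ok]
    grp = np.asarray(panel.groups)[ok]
    labels = pd.unique(grp)
    if len(labels) < 2:
        raise ValueError("need at least two admixture groups")
    if np.allclose(g, g[0]):
        raise ValueError(f"SNP {snp_id}: constant dosage; nothing to test")
    x = np.column_stack([np.ones_like(g), g])
    x_groups = [x[grp == lab] for lab in labels]
    y_groups = [y[grp == lab] for lab in labels]

    def objective(log_lam: float) -> float:
        return _profile_negloglik(np.exp(log_lam), x_groups, y_groups)[0]

    res = optimize.minimize_scalar(
        objective, bounds=(-25.0, 10.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam_hat = float(np.exp(res.x))
    # compare against the boundary lambda = 0 (no group variance)
    nll0, *_ = _profile_negloglik(0.0, x_groups, y_groups)
    if nll0 <= res.fun:
        lam_hat = 0.0
    nll, beta, a, sigma2_e = _profile_negloglik(lam_hat, x_groups, y_groups)
    sigma2_g = lam_hat * sigma2_e
    cov_beta = sigma2_e * np.linalg.inv(a)
    se = float(np.sqrt(cov_beta[1, 1]))
    z = beta[1] / se
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    var_g = float(np.var(g, ddof=1))
    fixed_var = beta[1] ** 2 * var_g
    ve = 100.0 * fixed_var / (fixed_var + sigma2_g + sigma2_e)
    return LmmFit(
        snp_id=snp_id,
        intercept=float(beta[0]),
        beta=float(beta[1]),
        beta_se=se,
        p_value=p_value,
        sigma2_group=float(sigma2_g),
        sigma2_resid=float(sigma2_e),
        variance_explained=float(ve),
        log_likelihood=float(-nll),
        n=int(len(y)),
    )


def ld_r2(panel: GenotypePanel, snp_ids: list[str] | None = None) -> pd.DataFrame:
    """Composite linkage disequilibrium: squared Pearson correlation of
    dosage vectors over pairwise-complete ecotypes.  Entries involving a
    constant dosage vector are NaN."""
    ids = snp_ids if snp_ids is not None else list(panel.snp_ids)
    if len(ids) < 2:
        raise ValueError("need at least two SNPs for LD")
    cols = {s: panel.dosage(s) for s in ids}
    m = len(ids)
    out = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i, m):
            a, b = cols[ids[i]], cols[ids[j]]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < 2:
                continue
            aa, bb = a[ok], b[ok]
            if np.allclose(aa, aa[0]) or np.allclose(bb, bb[0]):
                continue
            r = np.corrcoef(aa, bb)[0, 1]
            out[i, j] = out[j, i] = r * r
    return pd.DataFrame(out, index=ids, columns=ids)
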