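"""Kinship estimators (scGRM, UKin, rGRM, KING-robust) and relationship calls.

All GRM-type estimators work on the genotype correlation scale
``rho = 2 phi``.  The sample-correlation GRM (scGRM) for a pair
``(i, i')`` averages per-SNP centered cross-products::

    rho_hat_ii' = (1/m) sum_j (X_ij - Xbar_j)(X_i'j - Xbar_j) / sigma_j^2

where ``Xbar_j`` is the mean dosage over the centering set and
``sigma_j^2`` the per-SNP genotype variance (known, sample, or HWE per
:class:`~ukin.genotypes.EstimatorConfig`).  Centering by the observed
mean makes ``rho_hat`` systematically biased downward; over all pairs its
sum is forced negative.  The UKin correction removes the bias using only
the scGRM matrix itself::

    rho_tilde_ii' = rho_hat_ii' + (1/2) sum_{k != i} rho_hat_ik
                                + (1/2) sum_{l != i'} rho_hat_li' + 1

which is unbiased for ``rho_ii'`` under known per-SNP variances.  Kinship
estimates are ``phi = rho / 2`` and are deliberately *not* truncated to
``[0, 0.5]``: negative estimates are part of what the bias analysis is
about.

The KING-robust comparator is a moment estimator from shared-heterozygote
and opposite-homozygote counts and does not use allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import EstimatorConfig, GenotypeMatrix, snp_stats

__all__ = [
    "KinshipMatrix",
    "RelationshipCall",
    "scgrm",
    "rgrm",
    "ukin",
    "king_robust",
    "classify_relationship",
    "ukin_per_snp",
    "write_kinship_matrix",
    "read_kinship_matrix",
    "write_grm_text",
    "read_grm_text",
]

# Relationship-degree thresholds on the kinship scale (powers of 2).
MZ_THRESHOLD = 2.0 ** -1.5        # ~0.3536
FIRST_DEGREE = 2.0 ** -2.5        # ~0.1768
SECOND_DEGREE = 2.0 ** -3.5       # ~0.0884
THIRD_DEGREE = 2.0 ** -4.5        # ~0.0442


@dataclass
class KinshipMatrix:
    """Symmetric matrix of pairwise kinship estimates on the phi scale.

    The diagonal is the estimator's formula applied with ``i = i'`` (the
    pairwise definitions leave it open; a full matrix is needed for REML),
    except KING whose diagonal is fixed at 0.5.  ``correlation()`` returns
    the ``rho = 2 phi`` scale.
    """

    phi: np.ndarray
    estimator: str
    sample_ids: list[str]
    config: Optional[EstimatorConfig] = None
    n_snps: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        n = self.phi.shape[0]
        if self.phi.shape != (n, n):
            raise ValueError("phi must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if not self.estimator:
            raise ValueError("estimator tag required")
        if not np.allclose(self.phi, self.phi.T, equal_nan=True):
            raise ValueError("phi must be symmetric")

    @property
    def n(self) -> int:
        return self.phi.shape[0]

    def correlation(self) -> np.ndarray:
        return 2.0 * self.phi

    def grm(self) -> np.ndarray:
        """GRM on the 2*phi scale (diagonal ~1), as used by REML."""
        return 2.0 * self.phi

    def offdiag(self) -> np.ndarray:
        i, j = np.triu_indices(self.n, k=1)
        return self.phi[i, j]


@dataclass
class RelationshipCall:
    id_a: str
    id_b: str
    degree: str
    phi_estimate: float


def _standardized(G: GenotypeMatrix, cfg: EstimatorConfig,
                  scale: bool = True) -> tuple[np.ndarray, np.ndarray, float]:
    """Centered (optionally variance-scaled) scores and kept-SNP mask.

    Monomorphic SNPs (zero sample variance over the centering set) and
    SNPs with undefined variance are dropped identically for every
    GRM-type estimator so comparisons share a SNP set.  Missing entries
    are mean-imputed (centered score 0) or rejected per the config.

    Returns ``(Z, kept, var_sum)`` where ``var_sum`` is the sum of the
    per-SNP variances over kept SNPs (used by rGRM).
    """
    cfg.validate(G.n_snps)
    if cfg.missing_policy == "error" and G.missing_mask.any():
        raise ValueError("matrix contains missing genotypes")
    stats = snp_stats(G, cfg.centering_set)
    kept = ~stats.undefined
    # SNPs monomorphic *within the analysis set* are dropped only when the
    # variance must be estimated from that same set (division by zero
    # otherwise).  With externally known variances they are retained: their
    # centered scores are 0, and excluding them would condition the SNP set
    # on within-set variability, which reintroduces bias.
    if cfg.variance_mode == "known":
        var = np.asarray(cfg.known_variances, dtype=float)
    elif cfg.variance_mode == "sample":
        var = stats.var_sample
        kept &= ~stats.monomorphic
    else:  # hwe
        var = stats.var_hwe
        kept &= var > 0
    if not kept.any():
        raise ValueError("all SNPs are monomorphic or unusable")
    X = G.dosages[:, kept].astype(np.float64)
    miss = G.missing_mask[:, kept]
    mu = stats.mean[kept]
    if miss.any():
        X[miss] = np.broadcast_to(mu, X.shape)[miss]
    X -= mu  # in place: X now holds centered scores
    v = var[kept]
    if scale:
        X /= np.sqrt(v)
    return X, kept, float(v.sum())


def scgrm(G: GenotypeMatrix,
          cfg: Optional[EstimatorConfig] = None) -> KinshipMatrix:
    """Sample-correlation GRM: equal-weight average of per-SNP correlations."""
    cfg = cfg or EstimatorConfig()
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    Z, kept, _ = _standardized(G, cfg, scale=True)
    m = int(kept.sum())
    rho = (Z @ Z.T) / m
    return KinshipMatrix(rho / 2.0, "scgrm", list(G.sample_ids), cfg,
                         n_snps=m, meta={"diagonal": "pair formula with i=i'"})


def rgrm(G: GenotypeMatrix,
         cfg: Optional[EstimatorConfig] = None) -> KinshipMatrix:
    """GRM with SNP weights proportional to the genotype variance.

    Equivalent to summing raw centered cross-products and dividing by the
    summed per-SNP variances, so high-MAF SNPs carry more weight.
    """
    cfg = cfg or EstimatorConfig()
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    Zc, kept, var_sum = _standardized(G, cfg, scale=False)
    rho = (Zc @ Zc.T) / var_sum
    return KinshipMatrix(rho / 2.0, "rgrm", list(G.sample_ids), cfg,
                         n_snps=int(kept.sum()),
                         meta={"diagonal": "pair formula with i=i'"})


def ukin(scgrm_matrix: KinshipMatrix) -> KinshipMatrix:
    """UKin bias correction applied to an scGRM matrix.

    Off-diagonal entries add half of each member's off-diagonal row sum
    of ``rho_hat`` plus 1; the diagonal applies the same formula with
    ``i = i'`` (the row sum then enters once from each side).
    """
    if scgrm_matrix.estimator != "scgrm":
        raise ValueError("ukin expects an scGRM input matrix")
    rho = scgrm_matrix.correlation()
    n = rho.shape[0]
    if not np.allclose(rho, rho.T):
        raise ValueError("input matrix must be symmetric")
    r = rho.sum(axis=1) - np.diag(rho)  # off-diagonal row sums
    rho_t = rho + 0.5 * (r[:, None] + r[None, :]) + 1.0
    return KinshipMatrix(rho_t / 2.0, "ukin", list(scgrm_matrix.sample_ids),
                         scgrm_matrix.config, n_snps=scgrm_matrix.n_snps,
                         meta={"diagonal": "pair formula with i=i'",
                               "source": "scgrm"})


def ukin_per_snp(G: GenotypeMatrix,
                 cfg: Optional[EstimatorConfig] = None) -> KinshipMatrix:
    """UKin by direct per-SNP construction (independent code path).

    Averages the per-SNP corrected cross-products ``u^j_ii'`` over SNPs;
    algebraically identical to ``ukin(scgrm(G))`` and kept as a separate
    implementation for cross-validation.
    """
    cfg = cfg or EstimatorConfig()
    Z, kept, _ = _standardized(G, cfg, scale=True)
    n, m = Z.shape
    acc = np.zeros((n, n))
    for j in range(m):
        z = Z[:, j]
        c = np.outer(z, z)
        r = z * z.sum() - z * z  # sum_{k != i} z_i z_k
        u = c + 0.5 * (r[:, None] + r[None, :]) + 1.0
        acc += u
    rho_t = acc / m
    return KinshipMatrix(rho_t / 2.0, "ukin", list(G.sample_ids), cfg,
                         n_snps=m, meta={"path": "per-snp"})


def king_robust(G: GenotypeMatrix, block_size: int = 8192) -> KinshipMatrix:
    """KING-robust kinship from heterozygote/opposite-homozygote counts.

    For each pair, over the SNPs non-missing in both individuals::

        phi_hat = (N_AaAa - 2 N_AA,aa) / (N_Aa^(i) + N_Aa^(j))

    Pairs in which neither individual is heterozygous anywhere get NaN
    and are listed in ``meta["undefined_pairs"]``.  The diagonal is fixed
    at 0.5.  Counts are accumulated in float32 block matmuls (exact for
    counts below 2^24).
    """
    n, m = G.n_samples, G.n_snps
    if n < 2:
        raise ValueError("need at least 2 samples")
    has_missing = bool(G.missing_mask.any())
    n_het_shared = np.zeros((n, n), dtype=np.float32)
    n_opp = np.zeros((n, n), dtype=np.float32)
    den = np.zeros((n, n), dtype=np.float32) if has_missing else None
    for start in range(0, m, block_size):
        sl = slice(start, min(start + block_size, m))
        d = G.dosages[:, sl]
        obs = ~G.missing_mask[:, sl]
        het = ((d == 1) & obs).astype(np.float32)
        hom0 = ((d == 0) & obs).astype(np.float32)
        hom2 = ((d == 2) & obs).astype(np.float32)
        if has_missing:
            o = obs.astype(np.float32)
            heto = het  # het already requires observed
            # het count of i over SNPs observed in both i and j
            n_het_shared += heto @ heto.T
            n_opp += hom0 @ hom2.T + hom2 @ hom0.T
            # denominators need per-pair het counts over the shared set
            den += heto @ o.T + o @ heto.T
        else:
            n_het_shared += het @ het.T
            n_opp += hom0 @ hom2.T + hom2 @ hom0.T
    if has_missing:
        denom = den
    else:
        het_tot = ((G.dosages == 1) & ~G.missing_mask).sum(axis=1)
        denom = (het_tot[:, None] + het_tot[None, :]).astype(np.float64)
    num = n_het_shared.astype(np.float64) - 2.0 * n_opp.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, num / denom, np.nan)
    np.fill_diagonal(phi, 0.5)
    und = np.argwhere(np.isnan(np.triu(phi, k=1)) & (np.triu(np.ones_like(phi), 1) > 0))
    undefined = [(G.sample_ids[a], G.sample_ids[b]) for a, b in und]
    return KinshipMatrix(phi, "king", list(G.sample_ids), None, n_snps=m,
                         meta={"diagonal": "fixed 0.5",
                               "undefined_pairs": undefined})


def classify_relationship(phi: float, id_a: str = "a",
                          id_b: str = "b") -> RelationshipCall:
    """Degree call from a kinship estimate via power-of-2 thresholds.

    Intervals are half-open with the upper endpoint assigned to the more
    distant class, so an estimate exactly at a boundary goes to the lower
    degree deterministically.
    """
    if not np.isfinite(phi):
        raise ValueError("phi must be finite")
    if phi > MZ_THRESHOLD:
        degree = "MZ"
    elif phi > FIRST_DEGREE:
        degree = "first_degree"
    elif phi > SECOND_DEGREE:
        degree = "second_degree"
    elif phi > THIRD_DEGREE:
        degree = "third_degree"
    else:
        degree = "unrelated"
    return RelationshipCall(id_a, id_b, degree, float(phi))


# ---------------------------------------------------------------------------
# text formats


def write_kinship_matrix(K: KinshipMatrix, path: str | Path) -> None:
    """Square matrix text file with a header row/column of sample ids."""
    df = pd.DataFrame(K.phi, index=K.sample_ids, columns=K.sample_ids)
    with open(path, "w") as fh:
        fh.write(f"# estimator: {K.estimator}\n# n_snps: {K.n_snps}\n")
        df.to_csv(fh, sep="\t", index_label="id")


def read_kinship_matrix(path: str | Path) -> KinshipMatrix:
    estimator, n_snps = "unknown", 0
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            if key.strip() == "estimator":
                estimator = val.strip()
            elif key.strip() == "n_snps":
                n_snps = int(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return KinshipMatrix(df.to_numpy(), estimator,
                         [str(s) for s in df.index], n_snps=n_snps)


def write_grm_text(K: KinshipMatrix, prefix: str | Path) -> None:
    """GCTA-style lower-triangle GRM text: ``<prefix>.grm`` + ``.grm.id``.

    Rows are ``i j n_snps value`` with 1-based indices and the value on
    the GRM (``2 phi``) scale, plus an id file of ``fid iid`` pairs.
    """
    prefix = Path(prefix)
    grm = K.grm()
    n = K.n
    with open(f"{prefix}.grm", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{K.n_snps}\t{grm[i, j]:.10g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for sid in K.sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm_text(prefix: str | Path, estimator: str = "unknown",
                  ) -> KinshipMatrix:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in
           Path(f"{prefix}.grm.id").read_text().splitlines() if line.strip()]
    n = len(ids)
    grm = np.zeros((n, n))
    n_snps = 0
    for line in Path(f"{prefix}.grm").read_text().splitlines():
        if not line.strip():
            continue
        i, j, ns, val = line.split()
        grm[int(i) - 1, int(j) - 1] = grm[int(j) - 1, int(i) - 1] = float(val)
        n_snps = int(ns)
    return KinshipMatrix(grm / 2.0, estimator, ids, n_snps=n_snps)
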