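"""Genotype simulation with known relatedness by pedigree gene-dropping.

Founders receive two independent haplotypes per SNP with the reference
allele at frequency ``p_j ~ Uniform[maf_low, maf_high]``; every offspring
inherits one uniformly chosen haplotype from each parent, independently
across SNPs (linkage equilibrium).  Monozygotic (MZ) clones copy a
template individual's genotypes exactly.  Because transmission is exactly
Mendelian, every simulated pair realizes its pedigree IBD-sharing
probabilities ``(k0, k1, k2)`` and hence its kinship coefficient
``phi = k1/4 + k2/2``; the per-SNP genotype correlation of a pair equals
``2 phi``.

Ground truth is emitted as :class:`TrueKinship`, computed from the
pedigree by the standard recursive (tabular) kinship algorithm, not from
the realized genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = [
    "PedigreeSpec",
    "TrueKinship",
    "SimCohortConfig",
    "simulate_founders",
    "drop_pedigree",
    "simulate_mixed_cohort",
    "simulate_sib_families",
    "simulate_case_control",
    "simulate_phenotype",
]

# Table of IBD-sharing probabilities for the standard relative types
# (no inbreeding): phi, (k0, k1, k2).
IBD_TABLE = {
    "mz": (0.5, (0.0, 0.0, 1.0)),
    "parent_offspring": (0.25, (0.0, 1.0, 0.0)),
    "full_sib": (0.25, (0.25, 0.5, 0.25)),
    "half_sib": (0.125, (0.5, 0.5, 0.0)),
    "uncle_niece": (0.125, (0.5, 0.5, 0.0)),
    "first_cousin": (0.0625, (0.75, 0.25, 0.0)),
    "unrelated": (0.0, (1.0, 0.0, 0.0)),
}


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class PedigreeSpec:
    """A pedigree as founders + matings + MZ clones.

    Individuals are integer-indexed: founders ``0..founders-1``, then the
    offspring of each mating in order, then MZ clones in order.  ``emit``
    selects which individuals appear in the output genotype matrix
    (default: all).
    """

    founders: int
    matings: list[tuple[int, int, int]] = field(default_factory=list)
    mz_clones: list[tuple[int, int]] = field(default_factory=list)
    emit: Optional[list[int]] = None
    labels: dict[tuple[int, int], str] = field(default_factory=dict)

    def parents(self) -> list[Optional[tuple[int, int]]]:
        """Per-individual parent pair (None for founders), validating order."""
        out: list[Optional[tuple[int, int]]] = [None] * self.founders
        if self.founders < 0:
            raise ValueError("founder count must be >= 0")
        for pa, pb, n_off in self.matings:
            for _ in range(n_off):
                idx = len(out)
                if pa >= idx or pb >= idx or pa < 0 or pb < 0:
                    raise ValueError(
                        "parents must precede offspring (acyclic pedigree)")
                out.append((pa, pb))
        for tmpl, n_copies in self.mz_clones:
            for _ in range(n_copies):
                if tmpl >= len(out) or tmpl < 0:
                    raise ValueError("MZ template must precede its clones")
                out.append(None)  # clones handled separately
        return out

    @property
    def n_total(self) -> int:
        return (self.founders + sum(n for _, _, n in self.matings)
                + sum(n for _, n in self.mz_clones))

    def clone_map(self) -> dict[int, int]:
        """index -> template index for MZ clones."""
        out: dict[int, int] = {}
        idx = self.founders + sum(n for _, _, n in self.matings)
        for tmpl, n_copies in self.mz_clones:
            for _ in range(n_copies):
                out[idx] = tmpl
                idx += 1
        return out


@dataclass
class TrueKinship:
    """Ground-truth kinship for a simulated cohort.

    ``phi`` is the full ``n x n`` kinship matrix (diagonal 0.5 without
    inbreeding).  ``ibd_probs`` holds ``(k0, k1, k2)`` for the pairs the
    generator declares; any pair absent from it with ``phi == 0`` is
    unrelated, ``(1, 0, 0)``.
    """

    phi: np.ndarray
    ibd_probs: dict[tuple[int, int], tuple[float, float, float]] = field(
        default_factory=dict)
    sample_ids: Optional[list[str]] = None
    true_freqs: Optional[np.ndarray] = None  # simulator's per-SNP frequencies

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2 or self.phi.shape[0] != self.phi.shape[1]:
            raise ValueError("phi must be square")
        if self.ibd_probs:
            pairs = np.array(list(self.ibd_probs.keys()))
            ks = np.array(list(self.ibd_probs.values()))
            if not np.allclose(ks.sum(axis=1), 1.0):
                raise ValueError("IBD probabilities must sum to 1 per pair")
            expect = ks[:, 1] / 4.0 + ks[:, 2] / 2.0
            if not np.allclose(self.phi[pairs[:, 0], pairs[:, 1]], expect):
                raise ValueError("phi inconsistent with k1/4 + k2/2")

    @property
    def n(self) -> int:
        return self.phi.shape[0]

    def k(self, a: int, b: int) -> tuple[float, float, float]:
        key = (min(a, b), max(a, b))
        if key in self.ibd_probs:
            return self.ibd_probs[key]
        if self.phi[a, b] == 0.0:
            return (1.0, 0.0, 0.0)
        raise KeyError(f"IBD probabilities unknown for pair {key}")

    def correlation(self) -> np.ndarray:
        """True genotype correlation matrix rho = 2 phi (diagonal 1)."""
        rho = 2.0 * self.phi
        np.fill_diagonal(rho, 1.0)
        return rho

    def pair_table(self):
        """Three-column (id_a, id_b, phi) table of related pairs."""
        import pandas as pd
        ids = self.sample_ids or [str(i) for i in range(self.n)]
        a, b = np.triu_indices(self.n, k=1)
        rel = self.phi[a, b] > 0
        return pd.DataFrame({"id_a": [ids[i] for i in a[rel]],
                             "id_b": [ids[i] for i in b[rel]],
                             "phi": self.phi[a[rel], b[rel]]})

    def write(self, prefix) -> None:
        """Write ``<prefix>.pairs.tsv`` (related pairs) and
        ``<prefix>.phi.tsv`` (square matrix with id headers)."""
        import pandas as pd
        ids = self.sample_ids or [str(i) for i in range(self.n)]
        self.pair_table().to_csv(f"{prefix}.pairs.tsv", sep="\t",
                                 index=False)
        pd.DataFrame(self.phi, index=ids, columns=ids).to_csv(
            f"{prefix}.phi.tsv", sep="\t", index_label="id")


@dataclass
class SimCohortConfig:
    """Mixed-cohort design: counts of relative pairs by true kinship."""

    n_pairs_by_kinship: dict[float, int] = field(
        default_factory=lambda: {0.125: 500, 0.25: 500, 0.5: 500})
    n_singletons: int = 1000
    m: int = 50_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        for k, c in self.n_pairs_by_kinship.items():
            if k not in (0.125, 0.25, 0.5):
                raise ValueError(f"unsupported pair kinship {k}")
            if c < 0:
                raise ValueError("pair counts must be >= 0")
        if self.n_singletons < 0 or self.m < 1:
            raise ValueError("invalid cohort size")


def _draw_mafs(rng: np.random.Generator, m: int, maf_low: float,
               maf_high: float) -> np.ndarray:
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    return rng.uniform(maf_low, maf_high, size=m)


def simulate_founders(n: int, m: int, maf_low: float = 0.05,
                      maf_high: float = 0.5,
                      seed: int | np.random.Generator = 0,
                      ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Unrelated individuals in HWE at linkage equilibrium.

    Returns the genotype matrix and the true per-SNP reference-allele
    frequencies (drawn uniformly from ``[maf_low, maf_high]``, so the
    reference allele is the minor allele).
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    rng = _rng(seed)
    p = _draw_mafs(rng, m, maf_low, maf_high)
    dosages = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    G = GenotypeMatrix(dosages, np.zeros((n, m), bool),
                       [f"S{i}" for i in range(n)],
                       [f"snp{j}" for j in range(m)])
    return G, p


def _pedigree_phi(spec: PedigreeSpec) -> np.ndarray:
    """Kinship matrix by the recursive (tabular) method."""
    parents = spec.parents()
    clones = spec.clone_map()
    N = spec.n_total
    phi = np.zeros((N, N))
    for i in range(N):
        if i in clones:
            t = clones[i]
            phi[i, :i] = phi[t, :i]
            phi[:i, i] = phi[:i, t]
            phi[i, i] = phi[t, t]
            continue
        par = parents[i]
        if par is None:
            phi[i, i] = 0.5
        else:
            f, m_ = par
            phi[i, :i] = 0.5 * (phi[f, :i] + phi[m_, :i])
            phi[:i, i] = phi[i, :i]
            phi[i, i] = 0.5 * (1.0 + phi[f, m_])
    return phi


def _pedigree_ibd(spec: PedigreeSpec, phi: np.ndarray,
                  pairs: Sequence[tuple[int, int]],
                  ) -> dict[tuple[int, int], tuple[float, float, float]]:
    """(k0,k1,k2) for non-inbred pairs: k2 from parental kinships."""
    parents = spec.parents()
    clones = spec.clone_map()

    def k2(a: int, b: int) -> float:
        if clones.get(a) == b or clones.get(b) == a or (
                a in clones and b in clones and clones[a] == clones[b]):
            return 1.0
        if a in clones:
            return k2(clones[a], b)
        if b in clones:
            return k2(a, clones[b])
        pa, pb = parents[a], parents[b]
        if pa is None or pb is None:
            return 0.0
        (fa, ma), (fb, mb) = pa, pb
        return (phi[fa, fb] * phi[ma, mb] + phi[fa, mb] * phi[ma, fb])

    out = {}
    for a, b in pairs:
        a, b = min(a, b), max(a, b)
        kk2 = k2(a, b)
        kk1 = 4.0 * phi[a, b] - 2.0 * kk2
        out[(a, b)] = (1.0 - kk1 - kk2, kk1, kk2)
    return out


def drop_pedigree(spec: PedigreeSpec, m: int, maf_low: float = 0.05,
                  maf_high: float = 0.5,
                  seed: int | np.random.Generator = 0,
                  ) -> tuple[GenotypeMatrix, TrueKinship]:
    """Gene-drop genotypes through ``spec`` and return them with ground truth."""
    rng = _rng(seed)
    parents = spec.parents()
    clones = spec.clone_map()
    N = spec.n_total
    p = _draw_mafs(rng, m, maf_low, maf_high)
    haps = np.zeros((N, 2, m), dtype=np.int8)
    for i in range(N):
        if i in clones:
            haps[i] = haps[clones[i]]
        elif parents[i] is None:
            haps[i] = (rng.random((2, m)) < p).astype(np.int8)
        else:
            f, m_ = parents[i]
            pick_f = rng.integers(0, 2, size=m)
            pick_m = rng.integers(0, 2, size=m)
            haps[i, 0] = np.take_along_axis(
                haps[f], pick_f[None, :], axis=0)[0]
            haps[i, 1] = np.take_along_axis(
                haps[m_], pick_m[None, :], axis=0)[0]
    emit = spec.emit if spec.emit is not None else list(range(N))
    dosages = haps[emit].sum(axis=1, dtype=np.int8)
    n = len(emit)
    G = GenotypeMatrix(dosages, np.zeros((n, m), bool),
                       [f"S{i}" for i in emit],
                       [f"snp{j}" for j in range(m)])
    phi_full = _pedigree_phi(spec)
    phi = phi_full[np.ix_(emit, emit)]
    pos = {ind: k for k, ind in enumerate(emit)}
    related = [(a, b) for ai, a in enumerate(emit) for b in emit[ai + 1:]
               if phi_full[a, b] > 0]
    ibd_full = _pedigree_ibd(spec, phi_full, related)
    ibd = {(min(pos[a], pos[b]), max(pos[a], pos[b])): v
           for (a, b), v in ibd_full.items()}
    truth = TrueKinship(phi, ibd, sample_ids=G.sample_ids, true_freqs=p)
    return G, truth


def simulate_sib_families(n_families: int, family_size: int, m: int,
                          maf_low: float = 0.05, maf_high: float = 0.5,
                          seed: int | np.random.Generator = 0,
                          ) -> tuple[list[tuple[GenotypeMatrix, TrueKinship]],
                                     np.ndarray]:
    """Mutually unrelated full-sib families; only the siblings are emitted.

    Each family has two unobserved founder parents and ``family_size``
    full-sib offspring; within a family every pair has true kinship 0.25.
    All families share one per-SNP frequency vector (drawn once), which is
    returned as the pooled true MAFs.
    """
    if family_size < 2:
        raise ValueError("family_size must be >= 2")
    rng = _rng(seed)
    p = _draw_mafs(rng, m, maf_low, maf_high)
    out = []
    phi = np.full((family_size, family_size), 0.25)
    np.fill_diagonal(phi, 0.5)
    ibd = {(a, b): IBD_TABLE["full_sib"][1]
           for a in range(family_size) for b in range(a + 1, family_size)}
    for f in range(n_families):
        fat = (rng.random((2, m)) < p).astype(np.int8)
        mot = (rng.random((2, m)) < p).astype(np.int8)
        pick_f = rng.integers(0, 2, size=(family_size, m))
        pick_m = rng.integers(0, 2, size=(family_size, m))
        dosages = (np.take_along_axis(fat[None, :, :].repeat(family_size, 0),
                                      pick_f[:, None, :], axis=1)[:, 0, :]
                   + np.take_along_axis(mot[None, :, :].repeat(family_size, 0),
                                        pick_m[:, None, :], axis=1)[:, 0, :]
                   ).astype(np.int8)
        G = GenotypeMatrix(dosages, np.zeros_like(dosages, bool),
                           [f"F{f}_S{i}" for i in range(family_size)],
                           [f"snp{j}" for j in range(m)])
        out.append((G, TrueKinship(phi.copy(), dict(ibd),
                                   sample_ids=G.sample_ids, true_freqs=p)))
    return out, p


def simulate_mixed_cohort(cfg: SimCohortConfig,
                          ) -> tuple[GenotypeMatrix, TrueKinship, np.ndarray]:
    """Cohort of relative pairs plus singletons, all pairs mutually unrelated.

    Kinship-0.125 pairs are half-sibs, 0.25 pairs full sibs, 0.5 pairs MZ
    twins; different pairs share no founders.  Returns genotypes, ground
    truth, and the true per-SNP reference-allele frequencies.
    """
    cfg.validate()
    rng = _rng(cfg.seed)
    n_hs = cfg.n_pairs_by_kinship.get(0.125, 0)
    n_fs = cfg.n_pairs_by_kinship.get(0.25, 0)
    n_mz = cfg.n_pairs_by_kinship.get(0.5, 0)
    n = 2 * (n_hs + n_fs + n_mz) + cfg.n_singletons
    if n < 1:
        raise ValueError("empty cohort")
    m = cfg.m
    p = _draw_mafs(rng, m, cfg.maf_low, cfg.maf_high)
    dosages = np.empty((n, m), dtype=np.int8)

    block = max(1, min(m, 2_000_000 // max(n, 1) * 100))  # ~SNP blocks
    block = min(m, max(block, 1000))
    row = 0
    pair_rows: dict[float, list[tuple[int, int]]] = {0.125: [], 0.25: [], 0.5: []}
    for _ in range(n_hs):
        pair_rows[0.125].append((row, row + 1)); row += 2
    for _ in range(n_fs):
        pair_rows[0.25].append((row, row + 1)); row += 2
    for _ in range(n_mz):
        pair_rows[0.5].append((row, row + 1)); row += 2
    single_rows = list(range(row, n))

    def hap(shape, pb):
        return (rng.random(shape) < pb).astype(np.int8)

    for start in range(0, m, block):
        sl = slice(start, min(start + block, m))
        B = sl.stop - sl.start
        pb = p[sl]
        # half-sib pairs: shared parent + two independent other parents
        if n_hs:
            shared = hap((n_hs, 2, B), pb)
            othA = hap((n_hs, 2, B), pb)
            othB = hap((n_hs, 2, B), pb)
            pickS1 = rng.integers(0, 2, size=(n_hs, 1, B))
            pickS2 = rng.integers(0, 2, size=(n_hs, 1, B))
            pickA = rng.integers(0, 2, size=(n_hs, 1, B))
            pickB = rng.integers(0, 2, size=(n_hs, 1, B))
            c1 = (np.take_along_axis(shared, pickS1, 1)[:, 0]
                  + np.take_along_axis(othA, pickA, 1)[:, 0])
            c2 = (np.take_along_axis(shared, pickS2, 1)[:, 0]
                  + np.take_along_axis(othB, pickB, 1)[:, 0])
            rows = np.array(pair_rows[0.125])
            dosages[rows[:, 0], sl] = c1
            dosages[rows[:, 1], sl] = c2
        # full-sib pairs
        if n_fs:
            fat = hap((n_fs, 2, B), pb)
            mot = hap((n_fs, 2, B), pb)
            rows = np.array(pair_rows[0.25])
            for child in range(2):
                pf = rng.integers(0, 2, size=(n_fs, 1, B))
                pm = rng.integers(0, 2, size=(n_fs, 1, B))
                c = (np.take_along_axis(fat, pf, 1)[:, 0]
                     + np.take_along_axis(mot, pm, 1)[:, 0])
                dosages[rows[:, child], sl] = c
        # MZ pairs: one HWE draw, duplicated
        if n_mz:
            tmpl = rng.binomial(2, pb, size=(n_mz, B)).astype(np.int8)
            rows = np.array(pair_rows[0.5])
            dosages[rows[:, 0], sl] = tmpl
            dosages[rows[:, 1], sl] = tmpl
        if single_rows:
            dosages[single_rows[0]:, sl] = rng.binomial(
                2, pb, size=(len(single_rows), B)).astype(np.int8)

    phi = np.zeros((n, n))
    np.fill_diagonal(phi, 0.5)
    ibd: dict[tuple[int, int], tuple[float, float, float]] = {}
    for kin, rel in ((0.125, "half_sib"), (0.25, "full_sib"), (0.5, "mz")):
        for a, b in pair_rows[kin]:
            phi[a, b] = phi[b, a] = kin
            ibd[(a, b)] = IBD_TABLE[rel][1]
    G = GenotypeMatrix(dosages, np.zeros((n, m), bool),
                       [f"S{i}" for i in range(n)],
                       [f"snp{j}" for j in range(m)])
    truth = TrueKinship(phi, ibd, sample_ids=G.sample_ids, true_freqs=p)
    return G, truth, p


def simulate_case_control(n_cases: int, n_controls: int, m: int,
                          risk_prop: float = 0.05, shift_sd: float = 0.05,
                          maf_low: float = 0.05, maf_high: float = 0.5,
                          seed: int | np.random.Generator = 0,
                          ) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Case-control cohort with allele-frequency shifts at risk SNPs.

    Non-risk SNPs share one MAF between cases and controls; each risk SNP's
    case MAF is the control MAF plus a ``N(0, shift_sd^2)`` perturbation,
    clamped to ``[0.05, 0.95]``.  Returns genotypes, a boolean case label
    vector, and the risk-SNP indices.
    """
    if not 0.0 <= risk_prop <= 1.0:
        raise ValueError("risk_prop must lie in [0, 1]")
    rng = _rng(seed)
    p_ctrl = _draw_mafs(rng, m, maf_low, maf_high)
    n_risk = int(round(m * risk_prop))
    risk_idx = rng.choice(m, size=n_risk, replace=False)
    risk_idx.sort()
    p_case = p_ctrl.copy()
    if n_risk:
        p_case[risk_idx] = np.clip(
            p_ctrl[risk_idx] + rng.normal(0.0, shift_sd, size=n_risk),
            0.05, 0.95)
    n = n_cases + n_controls
    dosages = np.empty((n, m), dtype=np.int8)
    dosages[:n_cases] = rng.binomial(2, p_case, size=(n_cases, m))
    dosages[n_cases:] = rng.binomial(2, p_ctrl, size=(n_controls, m))
    labels = np.zeros(n, dtype=bool)
    labels[:n_cases] = True
    G = GenotypeMatrix(dosages, np.zeros((n, m), bool),
                       [f"case{i}" for i in range(n_cases)]
                       + [f"ctrl{i}" for i in range(n_controls)],
                       [f"snp{j}" for j in range(m)])
    return G, labels, risk_idx


def simulate_phenotype(G: GenotypeMatrix, h2: float,
                       causal_prop: float = 0.01,
                       seed: int | np.random.Generator = 0,
                       ) -> tuple[np.ndarray, dict]:
    """Additive polygenic phenotype with SNP-heritability ``h2``.

    Causal SNPs are chosen uniformly at random; effects on standardized
    dosages are i.i.d. ``N(0, h2 / m_causal)`` so the genetic component
    has variance ``h2`` in expectation, and the residual is
    ``N(0, 1 - h2)``; total phenotypic variance is approximately 1.
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must lie in [0, 1)")
    rng = _rng(seed)
    m = G.n_snps
    mc = int(round(m * causal_prop))
    if mc == 0 and h2 > 0:
        raise ValueError("causal count is 0 with h2 > 0")
    n = G.n_samples
    if mc > 0 and h2 > 0:
        causal = rng.choice(m, size=mc, replace=False)
        causal.sort()
        X = G.dosages[:, causal].astype(float)
        if np.any(G.missing_mask[:, causal]):
            Xn = X.copy()
            Xn[G.missing_mask[:, causal]] = np.nan
            mu = np.nanmean(Xn, axis=0)
            X[G.missing_mask[:, causal]] = np.take(
                mu, np.where(G.missing_mask[:, causal])[1])
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        beta = rng.normal(0.0, np.sqrt(h2 / mc), size=mc)
        g = Z @ beta
    else:
        causal = np.array([], dtype=int)
        beta = np.array([])
        g = np.zeros(n)
    e = rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
    y = g + e
    return y, {"causal_idx": causal, "beta": beta, "genetic": g}
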