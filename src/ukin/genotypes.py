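"""Genotype data model, PLINK-format I/O, quality control, and per-SNP statistics.

The central container is :class:`GenotypeMatrix`, an ``n x m`` matrix of
reference-allele dosages ``X_ij in {0, 1, 2}`` with an explicit missingness
mask.  Dosages count copies of the *first* allele listed in ``snp_alleles``
(the reference label), matching the convention that PLINK counts the A1
allele of each variant.

Supported on-disk formats:

* PLINK text ``.ped``/``.map``
* PLINK binary ``.bed``/``.bim``/``.fam`` (SNP-major, magic ``6C 1B 01``)
* a plain tab-separated dosage table (header row of SNP ids, first column
  of sample ids, ``NA`` for missing)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SnpStats",
    "EstimatorConfig",
    "QCReport",
    "load_genotypes",
    "write_genotypes",
    "qc_filter",
    "snp_stats",
]

_BED_MAGIC = b"\x6c\x1b\x01"


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosage matrix with metadata.

    Attributes
    ----------
    dosages : ndarray of int8, shape (n, m)
        Reference-allele counts; entries under ``missing_mask`` are 0 but
        carry no information.
    missing_mask : ndarray of bool, shape (n, m)
    sample_ids, snp_ids : lists of unique string identifiers.
    snp_alleles : list of (reference, alternate) allele labels per SNP.
    """

    dosages: np.ndarray
    missing_mask: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    snp_alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.dosages.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one sample and one SNP")
        if self.missing_mask.shape != (n, m):
            raise ValueError("missing_mask shape mismatch")
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("id list length mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        if not self.snp_alleles:
            self.snp_alleles = [("A", "B")] * m
        if len(self.snp_alleles) != m:
            raise ValueError("snp_alleles length mismatch")
        observed = self.dosages[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def dosage_float(self) -> np.ndarray:
        """Dosages as float64 with missing entries set to NaN."""
        X = self.dosages.astype(np.float64)
        X[self.missing_mask] = np.nan
        return X

    def subset(self, samples: Optional[Sequence[int]] = None,
               snps: Optional[Sequence[int]] = None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        sj = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(si, sj)],
            missing_mask=self.missing_mask[np.ix_(si, sj)],
            sample_ids=[self.sample_ids[i] for i in si],
            snp_ids=[self.snp_ids[j] for j in sj],
            snp_alleles=[self.snp_alleles[j] for j in sj],
        )


@dataclass
class SnpStats:
    """Per-SNP summaries over a centering set (missing entries excluded).

    ``var_sample`` is the unbiased sample variance (divisor ``count - 1``);
    ``var_hwe`` is the Hardy-Weinberg variance ``2 p (1 - p)`` at the
    observed reference-allele frequency ``p = mean / 2``.  SNPs with fewer
    than two non-missing values have undefined variance (NaN) and are
    flagged in ``undefined``.
    """

    mean: np.ndarray
    freq: np.ndarray
    var_sample: np.ndarray
    var_hwe: np.ndarray
    monomorphic: np.ndarray
    undefined: np.ndarray
    n_obs: np.ndarray


@dataclass
class EstimatorConfig:
    """How GRM-type estimators center and scale genotypes.

    variance_mode
        ``"known"`` uses user-supplied per-SNP variances (e.g. true
        ``2p(1-p)`` from a simulator or a reference panel), ``"sample"``
        the unbiased sample variance, ``"hwe"`` the variance implied by
        the observed allele frequency.
    missing_policy
        ``"mean_impute"`` replaces missing dosages by the centering-set
        mean before centering (the centered score is then exactly 0, so
        a missing genotype contributes nothing to any cross-product);
        ``"error"`` refuses matrices with missing entries.
    centering_set
        Sample indices over which per-SNP means (and sample variances)
        are computed; default all samples.
    """

    variance_mode: Literal["known", "sample", "hwe"] = "sample"
    known_variances: Optional[np.ndarray] = None
    missing_policy: Literal["mean_impute", "error"] = "mean_impute"
    centering_set: Optional[np.ndarray] = None

    def validate(self, m: int) -> None:
        if self.variance_mode not in ("known", "sample", "hwe"):
            raise ValueError(f"unknown variance_mode {self.variance_mode!r}")
        if self.missing_policy not in ("mean_impute", "error"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        if self.variance_mode == "known":
            if self.known_variances is None:
                raise ValueError("variance_mode='known' requires known_variances")
            kv = np.asarray(self.known_variances, dtype=float)
            if kv.shape != (m,):
                raise ValueError(f"known_variances must have length {m}")
            if not np.all(kv > 0):
                raise ValueError("known_variances must all be positive")


@dataclass
class QCReport:
    n_samples_in: int
    n_snps_in: int
    n_samples_removed_missing: int
    n_snps_removed_missing: int
    n_snps_removed_maf: int
    n_samples_out: int
    n_snps_out: int
    removed_sample_ids: list[str] = field(default_factory=list)
    removed_snp_ids: list[str] = field(default_factory=list)

    def as_text(self) -> str:
        lines = [
            f"samples_in: {self.n_samples_in}",
            f"snps_in: {self.n_snps_in}",
            f"samples_removed_missing: {self.n_samples_removed_missing}",
            f"snps_removed_missing: {self.n_snps_removed_missing}",
            f"snps_removed_maf: {self.n_snps_removed_maf}",
            f"samples_out: {self.n_samples_out}",
            f"snps_out: {self.n_snps_out}",
        ]
        return "\n".join(lines)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "key": ["samples_in", "snps_in", "samples_removed_missing",
                        "snps_removed_missing", "snps_removed_maf",
                        "samples_out", "snps_out"],
                "value": [self.n_samples_in, self.n_snps_in,
                          self.n_samples_removed_missing,
                          self.n_snps_removed_missing, self.n_snps_removed_maf,
                          self.n_samples_out, self.n_snps_out],
            }
        )


# ---------------------------------------------------------------------------
# per-SNP statistics and QC


def snp_stats(G: GenotypeMatrix,
              centering_set: Optional[Sequence[int]] = None) -> SnpStats:
    """Per-SNP mean, frequency and variances over ``centering_set``."""
    idx = (np.arange(G.n_samples) if centering_set is None
           else np.asarray(centering_set, dtype=int))
    if idx.size == 0:
        raise ValueError("centering_set must be non-empty")
    X = G.dosage_float()[idx]
    n_obs = np.sum(~np.isnan(X), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        mean = np.where(n_obs > 0, mean, np.nan)
    freq = mean / 2.0
    var_sample = np.full(G.n_snps, np.nan)
    ok = n_obs >= 2
    if np.any(ok):
        with np.errstate(invalid="ignore"):
            var_sample[ok] = np.nanvar(X[:, ok], axis=0, ddof=1)
    var_hwe = 2.0 * freq * (1.0 - freq)
    monomorphic = np.where(ok, var_sample == 0.0, False)
    undefined = ~ok
    return SnpStats(mean=mean, freq=freq, var_sample=var_sample,
                    var_hwe=var_hwe, monomorphic=monomorphic,
                    undefined=undefined, n_obs=n_obs)


def qc_filter(G: GenotypeMatrix, ind_miss_max: float = 0.10,
              snp_miss_max: float = 0.05,
              maf_min: float = 0.05) -> tuple[GenotypeMatrix, QCReport]:
    """Remove high-missingness individuals, then high-missingness / low-MAF SNPs.

    Individuals whose fraction of missing genotypes exceeds ``ind_miss_max``
    are removed first; SNP missing rates and minor allele frequencies are
    then recomputed on the remaining samples and SNPs failing either
    threshold are dropped.
    """
    for t in (ind_miss_max, snp_miss_max, maf_min):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    n, m = G.n_samples, G.n_snps
    ind_miss = G.missing_mask.mean(axis=1)
    keep_s = ind_miss <= ind_miss_max
    if not keep_s.any():
        raise ValueError("QC removed all samples")
    removed_samples = [sid for sid, k in zip(G.sample_ids, keep_s) if not k]
    G1 = G.subset(samples=np.where(keep_s)[0])

    snp_miss = G1.missing_mask.mean(axis=0)
    stats = snp_stats(G1)
    with np.errstate(invalid="ignore"):
        maf = np.fmin(stats.freq, 1.0 - stats.freq)
    fail_miss = snp_miss > snp_miss_max
    fail_maf = ~fail_miss & (np.isnan(maf) | (maf < maf_min))
    keep_j = ~(fail_miss | fail_maf)
    if not keep_j.any():
        raise ValueError("QC removed all SNPs")
    removed_snps = [sid for sid, k in zip(G1.snp_ids, keep_j) if not k]
    G2 = G1.subset(snps=np.where(keep_j)[0])
    report = QCReport(
        n_samples_in=n, n_snps_in=m,
        n_samples_removed_missing=int((~keep_s).sum()),
        n_snps_removed_missing=int(fail_miss.sum()),
        n_snps_removed_maf=int(fail_maf.sum()),
        n_samples_out=G2.n_samples, n_snps_out=G2.n_snps,
        removed_sample_ids=removed_samples, removed_snp_ids=removed_snps,
    )
    return G2, report


# ---------------------------------------------------------------------------
# file formats


def load_genotypes(path: str | Path,
                   format: Literal["ped_map", "bed_bim_fam", "dosage_table"],
                   ) -> GenotypeMatrix:
    """Read genotypes from disk.

    ``path`` is a file prefix for the PLINK formats (extensions are
    appended) and a file path for the dosage table.
    """
    if format == "ped_map":
        return _read_ped_map(Path(path))
    if format == "bed_bim_fam":
        return _read_bed(Path(path))
    if format == "dosage_table":
        return _read_dosage_table(Path(path))
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(G: GenotypeMatrix, path: str | Path,
                    format: Literal["ped_map", "bed_bim_fam", "dosage_table"],
                    ) -> None:
    if format == "ped_map":
        _write_ped_map(G, Path(path))
    elif format == "bed_bim_fam":
        _write_bed(G, Path(path))
    elif format == "dosage_table":
        _write_dosage_table(G, Path(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_map(map_path: Path) -> tuple[list[str], list[list[str]]]:
    snp_ids, rows = [], []
    for line in map_path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"malformed .map line: {line!r}")
        snp_ids.append(parts[1])
        rows.append(parts)
    return snp_ids, rows


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    snp_ids, _ = _read_map(prefix.with_suffix(".map"))
    m = len(snp_ids)
    sample_ids: list[str] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    for line in prefix.with_suffix(".ped").read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ValueError(
                f"ped row has {len(parts)} fields, expected {6 + 2 * m}")
        sample_ids.append(parts[1])
        allele_pairs.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)])
    n = len(sample_ids)
    if n == 0:
        raise ValueError("empty .ped file")
    # determine the two allele labels per SNP; reference = first non-zero
    # label seen (alphabetical tie-break for determinism)
    dosages = np.zeros((n, m), dtype=np.int8)
    missing = np.zeros((n, m), dtype=bool)
    snp_alleles: list[tuple[str, str]] = []
    for j in range(m):
        labels = sorted({a for i in range(n) for a in allele_pairs[i][j]
                         if a != "0"})
        if len(labels) > 2:
            raise ValueError(f"SNP {snp_ids[j]} has >2 allele codes: {labels}")
        if not labels:
            labels = ["A"]
        ref = labels[0]
        alt = labels[1] if len(labels) > 1 else "0"
        snp_alleles.append((ref, alt))
        for i in range(n):
            a1, a2 = allele_pairs[i][j]
            if a1 == "0" or a2 == "0":
                missing[i, j] = True
            else:
                dosages[i, j] = (a1 == ref) + (a2 == ref)
    return GenotypeMatrix(dosages, missing, sample_ids, snp_ids, snp_alleles)


def _write_ped_map(G: GenotypeMatrix, prefix: Path) -> None:
    with prefix.with_suffix(".map").open("w") as fh:
        for j, sid in enumerate(G.snp_ids):
            fh.write(f"1 {sid} 0 {j + 1}\n")
    with prefix.with_suffix(".ped").open("w") as fh:
        for i, sid in enumerate(G.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(G.n_snps):
                ref, alt = G.snp_alleles[j]
                if G.missing_mask[i, j]:
                    fields += ["0", "0"]
                else:
                    d = int(G.dosages[i, j])
                    fields += [ref] * d + [alt] * (2 - d)
            fh.write(" ".join(fields) + "\n")


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bim_ids, snp_alleles = [], []
    for line in prefix.with_suffix(".bim").read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"malformed .bim line: {line!r}")
        bim_ids.append(parts[1])
        snp_alleles.append((parts[4], parts[5]))  # A1 (counted), A2
    fam_ids = []
    for line in prefix.with_suffix(".fam").read_text().splitlines():
        if not line.strip():
            continue
        fam_ids.append(line.split()[1])
    n, m = len(fam_ids), len(bim_ids)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError("bad .bed magic bytes (expected 6C 1B 01, SNP-major)")
    stride = (n + 3) // 4
    if len(raw) - 3 != stride * m:
        raise ValueError(
            f".bed size {len(raw) - 3} does not match n={n}, m={m}")
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, stride)
    # unpack 2-bit genotypes, sample-fastest within byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, stride * 4)[:, :n].T  # (n, m)
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    dosages = np.zeros((n, m), dtype=np.int8)
    dosages[codes == 0] = 2
    dosages[codes == 2] = 1
    missing = codes == 1
    return GenotypeMatrix(dosages, missing, fam_ids, bim_ids, snp_alleles)


def _write_bed(G: GenotypeMatrix, prefix: Path) -> None:
    n, m = G.n_samples, G.n_snps
    with prefix.with_suffix(".bim").open("w") as fh:
        for j, sid in enumerate(G.snp_ids):
            ref, alt = G.snp_alleles[j]
            fh.write(f"1\t{sid}\t0\t{j + 1}\t{ref}\t{alt}\n")
    with prefix.with_suffix(".fam").open("w") as fh:
        for sid in G.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    codes = np.empty((m, n), dtype=np.uint8)
    d = G.dosages.T
    codes[d == 2] = 0
    codes[d == 1] = 2
    codes[d == 0] = 3
    codes[G.missing_mask.T] = 1
    stride = (n + 3) // 4
    padded = np.zeros((m, stride * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (padded[:, 0::4] | (padded[:, 1::4] << 2)
              | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6))
    with prefix.with_suffix(".bed").open("wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def _read_dosage_table(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    vals = df.to_numpy()
    missing = (vals == "NA") | pd.isna(vals)
    dosages = np.zeros(vals.shape, dtype=np.int8)
    obs = ~missing
    as_num = vals[obs].astype(float)
    if not np.all(np.isin(as_num, (0.0, 1.0, 2.0))):
        raise ValueError("dosage table entries must be 0/1/2 or NA")
    dosages[obs] = as_num.astype(np.int8)
    return GenotypeMatrix(dosages, missing,
                          [str(s) for s in df.index],
                          [str(s) for s in df.columns])


def _write_dosage_table(G: GenotypeMatrix, path: Path) -> None:
    vals = G.dosages.astype(object)
    vals[G.missing_mask] = "NA"
    df = pd.DataFrame(vals, index=G.sample_ids, columns=G.snp_ids)
    df.to_csv(path, sep="\t", index_label="sample_id")
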