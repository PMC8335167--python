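"""Synthetic GWAS study generator.

Emulates the statistical structure the gene-level tests assume: per-SNP
association z-scores that are multivariate normal with a block (within-gene)
LD correlation structure, uniform p-values under the null, and planted
non-centrality at one SNP in each designated risk gene.  Two simulation
levels are provided:

* **summary level** — z-scores drawn directly from the MVN law (fast; matches
  the null model of the gene tests exactly, so it is the right input for
  calibration studies);
* **genotype level** — 0/1/2 dosage matrices via latent-Gaussian
  thresholding, from which LD can be re-estimated and per-SNP allelic tests
  recomputed (validates the estimation path end to end).

The canonical within-gene LD structure is AR(1): corr(z_i, z_j) = rho^|i-j|.
It is single-parameter, spans independence (rho = 0) to near-perfect LD, and
is positive definite by construction.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.SeedSequence`` spawning: child streams are assigned in a fixed
documented order (one per gene for z-scores, then one per gene for the
genotype reference panel, then one for per-SNP allele frequencies), so any
stage can be re-run reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import (
    GeneRegion,
    GeneSetCollection,
    SnpAssocRecord,
    write_assoc,
    write_gene_ranges,
    write_gmt,
)

__all__ = [
    "LdMatrix",
    "SimulationConfig",
    "StudyPaths",
    "make_ld_matrix",
    "simulate_summary_z",
    "simulate_genotypes",
    "allelic_test",
    "allelic_test_p",
    "generate_study",
]

# floor for generated p-values: keeps them strictly positive and
# log-transformable by the Fisher combination
_P_FLOOR = 1e-300


@dataclass
class LdMatrix:
    """Pairwise SNP correlation matrix with its SNP ordering.

    Invariants: square, symmetric, unit diagonal.  Regularized matrices
    (see :func:`genewise.gene_tests.regularize_ld`) additionally have all
    eigenvalues at or above the regularization floor.
    """

    r: np.ndarray
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("LD matrix must be square")
        if len(self.snp_ids) != self.r.shape[0]:
            raise ValueError("snp_ids length must match matrix dimension")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have unit diagonal")

    @property
    def k(self) -> int:
        return self.r.shape[0]


def make_ld_matrix(k: int, rho: float, snp_ids: Sequence[str] | None = None) -> LdMatrix:
    """AR(1) LD matrix: entry (i, j) = rho^|i-j|.

    Positive definite for any 0 <= rho < 1 (eigenvalues of the Kac-Murdock-
    Szego matrix are bounded below by (1-rho)/(1+rho) > 0).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    idx = np.arange(k)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    if snp_ids is None:
        snp_ids = [f"s{i + 1}" for i in range(k)]
    return LdMatrix(r, list(snp_ids))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_summary_z(ld: LdMatrix, mu: Sequence[float], seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw one vector of association z-scores and two-sided p-values.

    z ~ MVN(mu, ld.r); p_i = 2 * Phi(-|z_i|), floored at 1e-300 so the
    output is always a valid association p-value.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (ld.k,):
        raise ValueError(f"mu has length {mu.shape}, LD dimension is {ld.k}")
    rng = _as_rng(seed)
    chol = np.linalg.cholesky(ld.r)
    z = mu + chol @ rng.standard_normal(ld.k)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR, 1.0)
    return z, p


def simulate_genotypes(ld: LdMatrix, maf: Sequence[float], n: int, seed) -> np.ndarray:
    """Simulate an (n x k) dosage matrix with the given LD and allele frequencies.

    Latent-Gaussian thresholding: each individual gets two independent
    haplotype draws from MVN(0, ld.r); haplotype h carries the minor allele
    at SNP j iff its latent value exceeds the upper-maf_j normal quantile.
    Column allele frequencies converge to ``maf`` and the dosage correlation
    approaches (an attenuated version of) the latent LD as n grows.
    """
    maf = np.asarray(maf, dtype=float)
    if maf.shape != (ld.k,):
        raise ValueError("maf length must match LD dimension")
    if np.any((maf <= 0.0) | (maf > 0.5)):
        raise ValueError("maf entries must lie in (0, 0.5]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    chol = np.linalg.cholesky(ld.r)
    thresh = stats.norm.isf(maf)  # P(latent > thresh) = maf
    latents = rng.standard_normal((2, n, ld.k)) @ chol.T
    return (latents > thresh).sum(axis=0).astype(np.int8)


def allelic_test(case_dosages: Sequence[int], control_dosages: Sequence[int]) -> tuple[float, float, bool]:
    """1-df chi-squared allelic test on the 2x2 allele-count table.

    Returns ``(statistic, p, monomorphic)``.  A monomorphic SNP (zero margin
    in the allele table) is not testable: the statistic is 0, p = 1, and the
    flag is set.
    """
    cases = np.asarray(case_dosages, dtype=float)
    controls = np.asarray(control_dosages, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    a = float(cases.sum())          # minor alleles, cases
    b = 2.0 * cases.size - a        # major alleles, cases
    c = float(controls.sum())       # minor alleles, controls
    d = 2.0 * controls.size - c
    n = a + b + c + d
    if (a + c) == 0 or (b + d) == 0:
        return 0.0, 1.0, True
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return stat, float(stats.chi2.sf(stat, df=1)), False


def allelic_test_p(case_dosages, control_dosages) -> float:
    """Allelic-test p-value only (see :func:`allelic_test`)."""
    return allelic_test(case_dosages, control_dosages)[1]


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------

def _default_causal() -> tuple[str, ...]:
    return ("G001", "G002", "G003", "G004", "G005")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic case-control GWAS summary study.

    Defaults emulate the scale of the NMOSD case study the pipeline was
    built around: a modest case series against a several-fold larger control
    panel, moderate within-gene LD, and a handful of strong risk genes each
    carrying one causal SNP.
    """

    n_genes: int = 50
    snps_per_gene: int | tuple[int, int] = 20
    block_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_cases: int = 215
    n_controls: int = 1244
    causal_genes: tuple[str, ...] = field(default_factory=_default_causal)
    effect_noncentrality: float = 6.0
    seed: int = 0
    n_reference: int = 400          # individuals in the LD reference panel
    write_reference_panel: bool = True
    snp_spacing_bp: int = 500
    inter_gene_gap_bp: int = 120_000   # > 2 x the 50 kb flank, so flanks never overlap

    def __post_init__(self) -> None:
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.effect_noncentrality < 0:
            raise ValueError("effect_noncentrality must be nonnegative")
        unknown = set(self.causal_genes) - set(self.gene_names)
        if unknown:
            raise ValueError(f"causal_genes not among generated genes: {sorted(unknown)}")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1:03d}" for i in range(self.n_genes)]


@dataclass
class StudyPaths:
    """File manifest returned by :func:`generate_study`."""

    assoc: Path
    glist: Path
    gmt: Path
    truth: Path
    reference_panel: Path | None


def _gene_snp_counts(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    if isinstance(config.snps_per_gene, int):
        return [config.snps_per_gene] * config.n_genes
    lo, hi = config.snps_per_gene
    return [int(x) for x in rng.integers(lo, hi + 1, size=config.n_genes)]


def _build_pathways(config: SimulationConfig) -> GeneSetCollection:
    """One pathway concentrating the causal genes plus size-filter edge cases.

    Decoy sizes 19/20 are drawn from null genes; decoys 300/301 contain the
    whole gene universe padded with off-universe names, so after universe
    intersection they coincide with the universe and can never be enriched.
    """
    genes = config.gene_names
    causal = list(config.causal_genes)
    nulls = [g for g in genes if g not in set(causal)]

    sets: list[tuple[str, str, list[str]]] = []
    target = 20
    pad = max(0, target - len(causal))
    sets.append(("PW_CAUSAL", "planted risk pathway", causal + nulls[:pad]))
    if len(nulls) >= 19:
        sets.append(("PW_DECOY19", "below size filter", nulls[-19:]))
    if len(nulls) >= 20:
        sets.append(("PW_DECOY20", "at lower size bound", nulls[-20:]))
    filler300 = [f"OFFUNIVERSE{i:04d}" for i in range(max(0, 300 - len(genes)))]
    filler301 = [f"OFFUNIVERSE{i:04d}" for i in range(max(0, 301 - len(genes)))]
    sets.append(("PW_DECOY300", "at upper size bound", genes + filler300))
    sets.append(("PW_DECOY301", "above size filter", genes + filler301))
    return GeneSetCollection(sets)


def generate_study(config: SimulationConfig, out_dir: str | Path) -> StudyPaths:
    """Generate a complete synthetic study on disk.

    Writes an association summary table, a glist gene annotation, a GMT
    pathway file, a truth table (gene, is_causal, noncentrality) and — unless
    disabled — a genotype reference panel TSV (rows = individuals, columns =
    SNPs) drawn from the same LD law for LD re-estimation.  Genes are laid
    out non-overlapping on one synthetic chromosome with inter-gene gaps
    exceeding twice the default mapping flank.  Fixed seed gives
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(config.seed)
    z_seeds = root.spawn(config.n_genes)
    panel_seeds = root.spawn(config.n_genes)
    misc_rng = np.random.default_rng(root.spawn(1)[0])

    counts = _gene_snp_counts(config, misc_rng)
    causal = set(config.causal_genes)

    regions: list[GeneRegion] = []
    records: list[SnpAssocRecord] = []
    panel_cols: list[np.ndarray] = []
    snp_ids_all: list[str] = []

    cursor = 1
    for i, gene in enumerate(config.gene_names):
        k = counts[i]
        start = cursor
        end = start + (k - 1) * config.snp_spacing_bp
        cursor = end + config.inter_gene_gap_bp
        regions.append(GeneRegion(gene, "1", start, max(end, start)))

        ld = make_ld_matrix(k, config.block_rho)
        mu = np.zeros(k)
        if gene in causal:
            mu[k // 2] = config.effect_noncentrality
        _z, p = simulate_summary_z(ld, mu, np.random.default_rng(z_seeds[i]))

        for j in range(k):
            snp_id = f"{gene}_s{j + 1:03d}"
            snp_ids_all.append(snp_id)
            records.append(SnpAssocRecord(snp_id, "1", start + j * config.snp_spacing_bp, float(p[j])))

        if config.write_reference_panel:
            maf = misc_rng.uniform(*config.maf_range, size=k)
            panel_cols.append(simulate_genotypes(ld, maf, config.n_reference,
                                                 np.random.default_rng(panel_seeds[i])))

    assoc_path = out_dir / "assoc.tsv"
    glist_path = out_dir / "genes.glist"
    gmt_path = out_dir / "pathways.gmt"
    truth_path = out_dir / "truth.tsv"
    write_assoc(records, assoc_path)
    write_gene_ranges(regions, glist_path)
    write_gmt(_build_pathways(config), gmt_path)
    with open(truth_path, "w") as fh:
        fh.write("gene\tis_causal\tnoncentrality\n")
        for gene in config.gene_names:
            nc = config.effect_noncentrality if gene in causal else 0.0
            fh.write(f"{gene}\t{int(gene in causal)}\t{nc:g}\n")

    panel_path: Path | None = None
    if config.write_reference_panel:
        panel_path = out_dir / "reference_panel.tsv"
        panel = np.concatenate(panel_cols, axis=1)
        with open(panel_path, "w") as fh:
            fh.write("\t".join(snp_ids_all) + "\n")
            for row in panel:
                fh.write("\t".join(str(int(x)) for x in row) + "\n")

    return StudyPaths(assoc_path, glist_path, gmt_path, truth_path, panel_path)
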