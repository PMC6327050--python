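"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of a `SimulationConfig` (including its
seed) and draws from its own deterministic stream, so identical configs
reproduce identical outputs.  Defaults mirror the dimensions of the study
the pipeline is built around: an 824-case / 5200-control GWAS with a
common risk allele at OR 1.45; an expression cohort of 60 blasts of which
44 are disomic for the focal chromosome, with a 1.8-fold risk-homozygote
effect; ChIP allelic pileups at depth 100; a 117-sample blast cohort with a
driver gene, 150 latent-factor targets and a 150-gene DE label set; two
translocated cases planted at Z = 4.6; breakpoint flanks carrying canonical
RSS elements; and 313 peaks with 83/313 of TSSs placed within 1 kb.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allelic import PileupRecord
from .annotate import GenomicInterval, TssRecord
from .breakpoints import HEPTAMER, NONAMER

__all__ = [
    "SimulationConfig",
    "TruthBundle",
    "AllelicReadSim",
    "simulate_case_control",
    "simulate_posteriors",
    "simulate_ld_proxies",
    "simulate_eqtl",
    "simulate_allelic_reads",
    "simulate_expression_cohort",
    "simulate_translocated_cases",
    "simulate_breakpoint_locus",
    "simulate_peaks_tss",
]

# stream offsets keep generators independent under one config seed
_STREAMS = {
    "case_control": 1, "posteriors": 2, "eqtl": 3, "allelic": 4,
    "cohort": 5, "translocated": 6, "breakpoint": 7, "peaks": 8,
    "ld_proxies": 9,
}


class InvalidConfig(ValueError):
    """A simulation parameter is outside its stated range."""


@dataclass
class SimulationConfig:
    seed: int = 0
    # case/control GWAS
    n_cases: int = 824
    n_controls: int = 5200
    maf: float = 0.3
    odds_ratio: float = 1.45
    certainty: float = 0.95          # posterior mass on the true genotype
    # eQTL cohort
    n_samples_expr: int = 60
    nondisomic_frac: float = 16 / 60  # 44 of 60 blasts disomic
    fold_per_risk_homozygote: float = 1.8
    expr_noise_sd: float = 0.5       # natural-log scale
    baseline_tpm: float = 50.0
    # allelic ChIP reads
    depth: int = 100
    true_alt_fraction: float = 0.5
    ref_bias: float = 1.0            # multiplicative retention advantage, >= 1
    # expression cohort / programs
    n_samples_cohort: int = 117
    n_genes: int = 2000
    n_correlated: int = 150
    target_rho: float = 0.8
    de_size: int = 150
    de_overlap: int = 40
    # translocated outliers
    n_translocated: int = 2
    target_z: float = 4.6
    # breakpoint locus
    flank_len: int = 1000
    plant_rss: bool = True
    heptamer_only: bool = False
    spacer_class: int = 12
    rss_offset: int = 10             # bp downstream of the junction
    # peaks / TSS
    n_peaks: int = 313
    n_tss: int = 313
    peak_tss_within_frac: float = 83 / 313
    peak_width: int = 200
    tss_window: int = 1000
    chrom_len: int = 2_000_000

    def __post_init__(self):
        counts = dict(n_cases=self.n_cases, n_controls=self.n_controls,
                      n_samples_expr=self.n_samples_expr, depth=self.depth,
                      n_samples_cohort=self.n_samples_cohort, n_genes=self.n_genes,
                      n_peaks=self.n_peaks, n_tss=self.n_tss)
        for name, v in counts.items():
            if v <= 0:
                raise InvalidConfig(f"{name} must be positive, got {v}")
        if not (0 < self.maf <= 0.5):
            raise InvalidConfig("maf must be in (0, 0.5]")
        if self.odds_ratio <= 0:
            raise InvalidConfig("odds_ratio must be positive")
        if not (1 / 3 < self.certainty <= 1):
            raise InvalidConfig("certainty must be in (1/3, 1]")
        if self.fold_per_risk_homozygote <= 0:
            raise InvalidConfig("fold_per_risk_homozygote must be positive")
        if not (0 < self.true_alt_fraction < 1):
            raise InvalidConfig("true_alt_fraction must be in (0, 1)")
        if self.ref_bias < 1:
            raise InvalidConfig("ref_bias must be >= 1")
        if not (0 <= self.nondisomic_frac < 1):
            raise InvalidConfig("nondisomic_frac must be in [0, 1)")
        if self.n_correlated >= self.n_genes:
            raise InvalidConfig("n_correlated must be below n_genes")
        if not (0 <= self.target_rho < 1):
            raise InvalidConfig("target_rho must be in [0, 1)")
        if self.de_overlap > min(self.de_size, self.n_correlated):
            raise InvalidConfig("de_overlap exceeds a set size")
        if self.de_size > self.n_genes - 1:
            raise InvalidConfig("de_size exceeds the non-driver gene count")
        if self.target_z < 0:
            raise InvalidConfig("target_z must be non-negative")
        if self.flank_len < 50:
            raise InvalidConfig("flank_len must be >= 50")
        if self.spacer_class not in (12, 23):
            raise InvalidConfig("spacer_class must be 12 or 23")
        if self.plant_rss and self.flank_len < self.rss_offset + 7 + self.spacer_class + 9 + 1:
            raise InvalidConfig("flank too short to contain the planted RSS")
        if not (0 <= self.peak_tss_within_frac <= 1):
            raise InvalidConfig("peak_tss_within_frac must be in [0, 1]")
        min_len = self.n_peaks * (self.peak_width + 4 * self.tss_window)
        if self.chrom_len < min_len:
            raise InvalidConfig("chromosome too small to place peaks and TSSs")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


class TruthBundle(dict):
    """Ground-truth record for a generated dataset (JSON-serialisable)."""

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"cannot serialise {type(o)}")
        with open(path, "w") as fh:
            json.dump(self, fh, indent=2, sort_keys=True, default=default)


# ---------------------------------------------------------------------------
# case/control genotypes

def simulate_case_control(config: SimulationConfig):
    """Biallelic risk SNP with a case/control allele-frequency shift.

    Controls are Hardy-Weinberg at frequency ``maf``; the case allele
    frequency is set so the allele-scale odds ratio equals
    ``odds_ratio`` exactly: odds_case = OR * odds_control.
    Returns (genotypes DataFrame samples x variants, phenotype Series,
    TruthBundle).
    """
    rng = config.rng("case_control")
    m = config.maf
    odds_case = config.odds_ratio * m / (1 - m)
    p_case = odds_case / (1 + odds_case)

    g_case = rng.binomial(2, p_case, size=config.n_cases)
    g_ctrl = rng.binomial(2, m, size=config.n_controls)
    samples = ([f"case_{i}" for i in range(config.n_cases)]
               + [f"ctrl_{i}" for i in range(config.n_controls)])
    geno = pd.DataFrame({"rs_lead": np.concatenate([g_case, g_ctrl])}, index=samples)
    pheno = pd.Series(np.r_[np.ones(config.n_cases, dtype=int),
                            np.zeros(config.n_controls, dtype=int)],
                      index=samples, name="phenotype")
    truth = TruthBundle(true_or=config.odds_ratio, control_af=m, case_af=p_case,
                        variant="rs_lead", seed=config.seed)
    return geno, pheno, truth


def simulate_posteriors(genotypes: pd.DataFrame, certainty: float,
                        seed: int = 0) -> dict[str, np.ndarray]:
    """Posterior genotype triples with ``certainty`` mass on the true call.

    The remaining mass is split evenly over the two other genotypes, so
    triples sum to one by construction.  Deterministic given the genotypes
    (the seed is accepted for interface symmetry).
    """
    if not (1 / 3 < certainty <= 1):
        raise InvalidConfig("certainty must be in (1/3, 1]")
    rest = (1.0 - certainty) / 2.0
    out = {}
    for var in genotypes.columns:
        g = genotypes[var].to_numpy(dtype=int)
        post = np.full((g.size, 3), rest)
        post[np.arange(g.size), g] = certainty
        out[var] = post
    return out


def simulate_ld_proxies(
    lead_dosage: np.ndarray,
    n_proxies: int,
    flip_prob: float,
    n_independent: int,
    maf: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Proxy variants in LD with a lead plus independent background variants.

    Each proxy copies the lead's alleles and flips each with probability
    ``flip_prob`` (lower flip_prob -> higher r^2); independents are
    Hardy-Weinberg at ``maf``.
    """
    rng = np.random.default_rng([seed, _STREAMS["ld_proxies"]])
    lead = np.asarray(lead_dosage, dtype=int)
    n = lead.size
    cols = {}
    for j in range(n_proxies):
        # flip at allele level: dosage d contributes d risk alleles of 2
        risk = rng.binomial(lead, 1 - flip_prob) + rng.binomial(2 - lead, flip_prob)
        cols[f"proxy_{j}"] = risk
    for j in range(n_independent):
        cols[f"indep_{j}"] = rng.binomial(2, maf, size=n)
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# eQTL cohort

def simulate_eqtl(genotypes: np.ndarray | None, config: SimulationConfig):
    """Expression cohort with a planted per-dosage log-additive eQTL effect.

    log TPM = log(baseline) + dosage * log(fold)/2 + N(0, sd); a
    ``nondisomic_frac`` share of samples is flagged copy-number 1 or 3 with
    expression scaled by cn/2.  Pass ``genotypes=None`` to draw genotypes
    Hardy-Weinberg at the configured MAF.
    Returns (DataFrame with columns sample/dosage/tpm/copy_number, truth).
    """
    rng = config.rng("eqtl")
    n = config.n_samples_expr
    if genotypes is None:
        dosage = rng.binomial(2, config.maf, size=n)
    else:
        dosage = np.asarray(genotypes, dtype=int)
        if dosage.size == 0:
            raise ValueError("empty genotype table")
        n = dosage.size

    log_fold = math.log(config.fold_per_risk_homozygote)
    log_expr = (math.log(config.baseline_tpm) + dosage * log_fold / 2.0
                + rng.normal(0.0, config.expr_noise_sd, size=n))

    n_nondisomic = int(round(config.nondisomic_frac * n))
    cn = np.full(n, 2, dtype=int)
    if n_nondisomic:
        idx = rng.choice(n, size=n_nondisomic, replace=False)
        cn[idx] = rng.choice([1, 3], size=n_nondisomic)
    tpm = np.exp(log_expr) * cn / 2.0

    table = pd.DataFrame({"sample": [f"blast_{i}" for i in range(n)],
                          "dosage": dosage, "tpm": tpm, "copy_number": cn})
    truth = TruthBundle(true_fold=config.fold_per_risk_homozygote,
                        disomic_samples=table.loc[table.copy_number == 2, "sample"].tolist(),
                        n_disomic=int((cn == 2).sum()), seed=config.seed)
    return table, truth


# ---------------------------------------------------------------------------
# allelic ChIP reads

@dataclass
class AllelicReadSim:
    """Per-read allelic evidence for one het site, assay plus input control.

    Reference-mapping bias is modelled as read loss: a read carrying the
    alternate allele fails to map with probability 1 - 1/ref_bias *unless*
    the site is N-masked in the reference.  ``pileup(masked=...)`` renders
    the pileup an aligner would produce under either reference.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    assay_reads: list[tuple[str, bool]]   # (base, lost_without_mask)
    input_reads: list[tuple[str, bool]]
    truth: TruthBundle = field(default_factory=TruthBundle)

    def pileup(self, assay: str = "assay", masked: bool = True) -> list[PileupRecord]:
        reads = self.assay_reads if assay == "assay" else self.input_reads
        out = []
        for i, (base, lost) in enumerate(reads):
            if lost and not masked:
                continue
            out.append(PileupRecord(self.chrom, self.pos, base, 40, 60,
                                    read_id=f"{assay}_{i}"))
        return out


def simulate_allelic_reads(config: SimulationConfig) -> AllelicReadSim:
    """Allelic read evidence with controllable imbalance and reference bias.

    Assay reads carry the alternate allele with probability
    ``true_alt_fraction``; input-control reads at 0.5 (genomic DNA of a
    het).  Without masking the observed alt fraction has expectation
    q = f / (f + (1-f) * ref_bias).
    """
    rng = config.rng("allelic")
    ref, alt = "A", "G"
    loss_p = 1.0 - 1.0 / config.ref_bias

    def draw(f: float) -> list[tuple[str, bool]]:
        is_alt = rng.random(config.depth) < f
        lost = is_alt & (rng.random(config.depth) < loss_p)
        return [(alt if a else ref, bool(l)) for a, l in zip(is_alt, lost)]

    truth = TruthBundle(true_alt_fraction=config.true_alt_fraction,
                        ref_bias=config.ref_bias,
                        expected_unmasked_alt_fraction=(
                            config.true_alt_fraction
                            / (config.true_alt_fraction
                               + (1 - config.true_alt_fraction) * config.ref_bias)),
                        seed=config.seed)
    return AllelicReadSim("chr14", 23_589_349, ref, alt,
                          draw(config.true_alt_fraction), draw(0.5), truth)


# ---------------------------------------------------------------------------
# expression cohort with a driver programme

def simulate_expression_cohort(config: SimulationConfig):
    """Blast cohort with a driver gene and a planted correlated gene set.

    A latent per-sample factor drives the driver gene and ``n_correlated``
    target genes at Pearson magnitude ``target_rho`` on the log scale; all
    other genes are independent.  A DE label list of ``de_size`` genes is
    planted with ``de_overlap`` members drawn from the correlated set.
    Returns (TPM DataFrame genes x samples, truth).
    """
    rng = config.rng("cohort")
    n, g = config.n_samples_cohort, config.n_genes
    z = rng.standard_normal(n)
    rho = config.target_rho

    genes = ["DRIVER"] + [f"G{i:05d}" for i in range(g - 1)]
    log_expr = np.empty((g, n))
    log_expr[0] = z  # driver log-expression is the latent factor itself
    corr_idx = 1 + np.arange(config.n_correlated)
    for i in range(1, g):
        eps = rng.standard_normal(n)
        if i in corr_idx:
            log_expr[i] = rho * z + math.sqrt(1 - rho**2) * eps
        else:
            log_expr[i] = eps
    base = rng.normal(math.log(config.baseline_tpm), 0.5, size=g)
    tpm = np.exp(base[:, None] + 0.6 * log_expr)

    expr = pd.DataFrame(tpm, index=genes,
                        columns=[f"blast_{i}" for i in range(n)])
    correlated = [genes[i] for i in corr_idx]
    pool = [genes[i] for i in range(1, g) if i not in corr_idx]
    de_from_corr = list(rng.choice(correlated, size=config.de_overlap, replace=False))
    de_from_rest = list(rng.choice(pool, size=config.de_size - config.de_overlap,
                                   replace=False))
    truth = TruthBundle(driver="DRIVER", correlated_genes=correlated,
                        de_genes=sorted(de_from_corr + de_from_rest),
                        target_rho=rho, seed=config.seed)
    return expr, truth


def simulate_translocated_cases(cohort: pd.DataFrame, config: SimulationConfig,
                                driver: str = "DRIVER"):
    """Append rare translocated cases with outlier driver expression.

    Each appended case's driver TPM equals cohort mean + target_z * cohort
    SD (sample SD, TPM scale); other genes are drawn from a per-gene
    log-normal fitted to the cohort.  Returns (expression with cases
    appended, boolean flag Series, truth).
    """
    if cohort.shape[1] == 0:
        raise ValueError("empty cohort")
    rng = config.rng("translocated")
    mean = cohort.loc[driver].mean()
    sd = cohort.loc[driver].std(ddof=1)
    planted = mean + config.target_z * sd

    log_c = np.log(cohort.to_numpy())
    mu, sigma = log_c.mean(axis=1), log_c.std(axis=1, ddof=1)
    cases = {}
    for j in range(config.n_translocated):
        vals = np.exp(rng.normal(mu, sigma))
        vals[cohort.index.get_loc(driver)] = planted
        cases[f"trans_{j}"] = vals
    out = pd.concat([cohort, pd.DataFrame(cases, index=cohort.index)], axis=1)
    flags = pd.Series(False, index=out.columns)
    flags[list(cases)] = True
    truth = TruthBundle(target_z=config.target_z, translocated_cases=sorted(cases),
                        planted_tpm=float(planted), seed=config.seed)
    return out, flags, truth


# ---------------------------------------------------------------------------
# breakpoint locus

def simulate_breakpoint_locus(config: SimulationConfig):
    """Breakpoint-spanning sequence with an optionally planted RSS.

    The sequence is ``2*flank_len + 1`` random bases with the junction at
    the centre (1-based position flank_len + 1).  With ``plant_rss`` the
    heptamer + spacer + nonamer (or heptamer only) is written into the
    downstream flank starting ``rss_offset`` bp past the junction.
    Returns (sequence, Breakpoint-compatible dict, truth).
    """
    rng = config.rng("breakpoint")
    length = 2 * config.flank_len + 1
    seq = rng.choice(list("ACGT"), size=length)
    bp_pos = config.flank_len + 1  # 1-based

    truth = TruthBundle(breakpoint_pos=bp_pos, planted=None, seed=config.seed)
    if config.plant_rss:
        spacer_len = config.spacer_class
        spacer = rng.choice(list("ACGT"), size=spacer_len)
        motif = list(HEPTAMER) + (list(spacer) if not config.heptamer_only else []) \
            + (list(NONAMER) if not config.heptamer_only else [])
        start0 = bp_pos + config.rss_offset  # 0-based: rss_offset bp into downstream flank
        if start0 + len(motif) > length:
            raise InvalidConfig("flank too short for the planted motif")
        seq[start0:start0 + len(motif)] = motif
        truth["planted"] = {
            "kind": "heptamer-only" if config.heptamer_only else "full-RSS",
            "start": int(start0),
            "spacer_class": None if config.heptamer_only else spacer_len,
            "offset_from_breakpoint": config.rss_offset,
        }
    sequence = "".join(seq)
    breakpoint = {"name": "bp_1", "chrom": "chr14", "position": bp_pos,
                  "orientation": "+"}
    return sequence, breakpoint, truth


# ---------------------------------------------------------------------------
# peaks and TSSs

def simulate_peaks_tss(config: SimulationConfig):
    """Peak intervals plus TSSs with a controlled fraction within 1 kb.

    Peaks are laid out on a regular grid with jitter so that inter-peak
    gaps always exceed twice the window; ``peak_tss_within_frac`` of genes
    get a TSS within the window of some peak, the rest strictly beyond it.
    Returns (peaks, tss records, truth with the exact within-window set).
    """
    rng = config.rng("peaks")
    w, win = config.peak_width, config.tss_window
    slot = config.chrom_len // config.n_peaks
    if slot < w + 4 * win:
        raise InvalidConfig("chromosome too small to place intervals")

    peaks = []
    for i in range(config.n_peaks):
        lo = i * slot + 2 * win
        hi = (i + 1) * slot - 2 * win - w
        start = int(rng.integers(lo, hi))
        peaks.append(GenomicInterval("chr14", start, start + w, name=f"peak_{i}"))

    n_within = int(round(config.peak_tss_within_frac * config.n_tss))
    within = set(rng.choice(config.n_tss, size=n_within, replace=False).tolist())
    tss = []
    for j in range(config.n_tss):
        peak = peaks[int(rng.integers(0, config.n_peaks))]
        if j in within:
            # anywhere from inside the peak to the inclusive window edge
            offset = int(rng.integers(-win, peak.end - peak.start + win))
            pos0 = peak.start + offset
        else:
            side = 1 if rng.random() < 0.5 else -1
            gap = int(rng.integers(win + 1, 2 * win))
            pos0 = (peak.end - 1 + gap) if side > 0 else (peak.start - gap)
        tss.append(TssRecord(f"gene_{j}", "chr14", pos0 + 1))
    truth = TruthBundle(within_genes=sorted(f"gene_{j}" for j in within),
                        window=win, seed=config.seed)
    return peaks, tss, truth
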