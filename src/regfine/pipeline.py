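"""End-to-end orchestration: simulate inputs, run every stage, write a summary.

The pipeline is file-driven: the simulate stage writes every input format
to ``<outdir>/inputs`` and the analysis stages read those files back, so a
simulated run exercises the same code paths as a run on real data.  The
summary report contains no timestamps; two runs with the same seed produce
byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as rio
from . import assoc as A
from . import eqtl as E
from . import allelic as AL
from . import qpcr as Q
from . import annotate as AN
from . import programs as P
from . import breakpoints as B
from .simulate import (
    SimulationConfig, simulate_case_control, simulate_posteriors,
    simulate_ld_proxies, simulate_eqtl, simulate_allelic_reads,
    simulate_expression_cohort, simulate_translocated_cases,
    simulate_breakpoint_locus, simulate_peaks_tss,
)

log = logging.getLogger("regfine")

STAGES = ["simulate", "assoc", "eqtl", "ase", "chipq", "annotate",
          "programs", "breakpoints"]


@dataclass
class RunConfig:
    """Resolved run configuration; unknown keys in a config file are rejected."""

    seed: int = 0
    outdir: str = "regfine_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulate: bool = True
    info_min: float = 0.8
    r2_min: float = 0.4
    maf_min: float = 0.01
    tss_window: int = 1000
    corr_p: float = 5e-4
    top_k: int = 150
    alpha: float = 0.05
    hic_resolution: int = 5000
    hic_threshold: float = 5.0
    sim: dict = field(default_factory=dict)  # overrides for SimulationConfig

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _dump_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"cannot serialise {type(o)}")
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


# ---------------------------------------------------------------------------
# simulate stage: write every downstream input as files

def stage_simulate(cfg: RunConfig, indir: Path) -> dict:
    sim = SimulationConfig(seed=cfg.seed, **cfg.sim)
    indir.mkdir(parents=True, exist_ok=True)

    # GWAS genotypes, phenotypes, posteriors, LD proxies
    geno, pheno, truth_cc = simulate_case_control(sim)
    proxies = simulate_ld_proxies(geno["rs_lead"].to_numpy(), n_proxies=5,
                                  flip_prob=0.05, n_independent=5,
                                  maf=sim.maf, seed=sim.seed)
    proxies.index = geno.index
    geno_all = pd.concat([geno, proxies], axis=1)
    post = simulate_posteriors(geno_all, sim.certainty, seed=sim.seed)
    rio.write_genotype_tsv(indir / "genotypes.tsv", geno_all, post)
    pheno.to_frame().to_csv(indir / "phenotypes.tsv", sep="\t", index_label="sample")
    truth_cc.to_json(indir / "truth_case_control.json")

    # eQTL cohort
    eq, truth_eq = simulate_eqtl(None, sim)
    expr = pd.DataFrame([eq.set_index("sample")["tpm"]], index=["CEBPE"])
    rio.write_expression_tsv(indir / "eqtl_expression.tsv", expr)
    eq_geno = pd.DataFrame({"rs_lead": eq["dosage"].to_numpy()},
                           index=eq["sample"])
    rio.write_genotype_tsv(indir / "eqtl_genotypes.tsv", eq_geno)
    eq.assign(chrom="chr14")[["sample", "chrom", "copy_number"]].to_csv(
        indir / "copy_number.tsv", sep="\t", index=False)
    truth_eq.to_json(indir / "truth_eqtl.json")

    # allelic ChIP reads: pileups under masked and unmasked references
    reads = simulate_allelic_reads(sim)
    for assay in ("assay", "input"):
        for masked in (True, False):
            tag = "masked" if masked else "unmasked"
            rio.write_pileup_tsv(indir / f"pileup_{assay}_{tag}.tsv",
                                 reads.pileup(assay, masked=masked))
    pd.DataFrame([{"site": "rs_lead", "chrom": reads.chrom, "pos": reads.pos,
                   "ref": reads.ref, "alt": reads.alt}]).to_csv(
        indir / "sites.tsv", sep="\t", index=False)
    reads.truth.to_json(indir / "truth_allelic.json")

    # ChIP-qPCR Cq table: 5-fold dilution standard curve (doubling chemistry),
    # a target with planted 8x enrichment over IgG, and a 300-fold
    # allele-preference primer pair
    slope = -1.0 / np.log10(2.0)
    rows = []
    for i, q in enumerate([100.0 / 5**j for j in range(5)]):
        rows.append({"target": "standard", "condition": f"dil_{i}",
                     "replicate": 1, "cq": 30.0 + slope * np.log10(q / 100.0)})
    curve_cq = lambda q: 30.0 + slope * np.log10(q / 100.0)
    rng = np.random.default_rng([cfg.seed, 90])
    for rep in range(1, 4):
        rows.append({"target": "locus", "condition": "antibody", "replicate": rep,
                     "cq": curve_cq(8.0) + rng.normal(0, 0.05)})
        rows.append({"target": "locus", "condition": "igg", "replicate": rep,
                     "cq": curve_cq(1.0) + rng.normal(0, 0.05)})
        rows.append({"target": "locus", "condition": "input", "replicate": rep,
                     "cq": curve_cq(100.0) + rng.normal(0, 0.05)})
    rows.append({"target": "allele_A", "condition": "matched", "replicate": 1,
                 "cq": curve_cq(300.0)})
    rows.append({"target": "allele_A", "condition": "mismatched", "replicate": 1,
                 "cq": curve_cq(1.0)})
    pd.DataFrame(rows).to_csv(indir / "qpcr_cq.tsv", sep="\t", index=False)

    # peaks, TSSs, Hi-C contacts
    peaks, tss, truth_pt = simulate_peaks_tss(sim)
    rio.write_bed(indir / "peaks.bed", peaks)
    rio.write_tss_tsv(indir / "tss.tsv", tss)
    truth_pt.to_json(indir / "truth_peaks_tss.json")
    res = cfg.hic_resolution
    bin_a = peaks[0].start // res
    bin_b = (tss[0].position - 1) // res
    contacts = pd.DataFrame({"bin_i": [bin_a, bin_a + 40],
                             "bin_j": [bin_b, bin_b + 60],
                             "value": [10.0, 1.0]})
    rio.write_contacts_tsv(indir / "contacts.tsv", contacts, "chr14", res)

    # expression cohort, translocated cases, DE table
    cohort, truth_cohort = simulate_expression_cohort(sim)
    full, flags, truth_tr = simulate_translocated_cases(cohort, sim)
    rio.write_expression_tsv(indir / "cohort_expression.tsv", full)
    flags.rename("translocated").to_frame().to_csv(
        indir / "sample_flags.tsv", sep="\t", index_label="sample")
    truth_cohort.to_json(indir / "truth_cohort.json")
    truth_tr.to_json(indir / "truth_translocated.json")
    de_rng = np.random.default_rng([cfg.seed, 91])
    de_genes = set(truth_cohort["de_genes"])
    others = [g for g in cohort.index if g != "DRIVER" and g not in de_genes]
    de_table = pd.DataFrame({
        "gene": list(de_genes) + others,
        "padj": np.r_[de_rng.uniform(1e-12, 1e-4, len(de_genes)),
                      de_rng.uniform(0.1, 1.0, len(others))],
        "log_fc": np.r_[de_rng.normal(0, 2, len(de_genes)),
                        de_rng.normal(0, 0.2, len(others))],
    })
    de_table.to_csv(indir / "de_table.tsv", sep="\t", index=False)

    # breakpoint locus
    seq, bp, truth_bp = simulate_breakpoint_locus(sim)
    rio.write_fasta(indir / "breakpoint_locus.fasta", {"locus": seq})
    pd.DataFrame([bp]).to_csv(indir / "breakpoints.tsv", sep="\t", index=False)
    truth_bp.to_json(indir / "truth_breakpoint.json")

    return {"n_input_files": len(list(indir.iterdir())),
            "sim_seed": sim.seed}


# ---------------------------------------------------------------------------
# analysis stages

def stage_assoc(cfg: RunConfig, indir: Path, outdir: Path) -> dict:
    geno, post = rio.read_genotype_tsv(indir / "genotypes.tsv")
    pheno = pd.read_csv(indir / "phenotypes.tsv", sep="\t", index_col="sample")
    pheno = pheno["phenotype"].reindex(geno.index)
    cases = geno[pheno == 1]
    controls = geno[pheno == 0]

    res = A.allelic_association(cases["rs_lead"], controls["rs_lead"], "rs_lead")

    # split-cohort fixed-effect meta-analysis with heterogeneity
    half_case = len(cases) // 2
    half_ctrl = len(controls) // 2
    studies = []
    for cs, ct in [(cases.iloc[:half_case], controls.iloc[:half_ctrl]),
                   (cases.iloc[half_case:], controls.iloc[half_ctrl:])]:
        r = A.allelic_association(cs["rs_lead"], ct["rs_lead"], "rs_lead")
        studies.append((r.beta, r.se))
    meta = A.fixed_effect_meta(studies)

    infos = {v: A.info_score(p, v) for v, p in (post or {}).items()}
    passing = A.info_filter(infos, cfg.info_min)
    capture = A.ld_block_capture("rs_lead", geno, cfg.r2_min, cfg.maf_min)
    cond = A.conditional_association(pheno.to_numpy(), geno["proxy_0"].to_numpy(),
                                    geno["rs_lead"].to_numpy())

    table = pd.DataFrame([{"variant": v, "beta": np.nan, "se": np.nan,
                           "or": np.nan, "p": np.nan,
                           "maf": min(geno[v].mean() / 2, 1 - geno[v].mean() / 2),
                           "info": infos[v].info if v in infos else np.nan}
                          for v in geno.columns]).set_index("variant")
    table.loc["rs_lead", ["beta", "se", "or", "p"]] = [res.beta, res.se,
                                                       res.odds_ratio, res.p]
    table.to_csv(outdir / "association.tsv", sep="\t")
    return {
        "lead_or": res.odds_ratio, "lead_p": res.p, "lead_beta": res.beta,
        "meta_or": meta.odds_ratio, "meta_p": meta.p, "p_het": meta.p_het,
        "n_info_pass": len(passing), "n_variants": geno.shape[1],
        "ld_block": sorted(capture.captured),
        "capture_fraction": capture.capture_fraction,
        "conditional_proxy_p": cond.p,
    }


def stage_eqtl(cfg: RunConfig, indir: Path, outdir: Path) -> dict:
    expr = rio.read_expression_tsv(indir / "eqtl_expression.tsv")
    geno, _ = rio.read_genotype_tsv(indir / "eqtl_genotypes.tsv")
    cn = rio.read_copy_number_tsv(indir / "copy_number.tsv")

    samples = [s for s in expr.columns]
    disomic = E.disomy_filter(samples, cn, chromosome="chr14")
    tpm = expr.loc["CEBPE", disomic].to_numpy(dtype=float)
    dosage = geno.loc[disomic, "rs_lead"].to_numpy(dtype=int)

    kw = E.kruskal_wallis_by_genotype(tpm, dosage)
    fold = E.homozygote_fold_change(
        {g: tpm[dosage == g] for g in (0, 1, 2)}, risk_dosage=2)
    pd.DataFrame([{"gene": "CEBPE", "H": kw.H, "p": kw.p, "fold": fold.fold,
                   "n_disomic": len(disomic),
                   **{f"n_g{g}": int((dosage == g).sum()) for g in (0, 1, 2)}}]
                 ).to_csv(outdir / "eqtl.tsv", sep="\t", index=False)
    return {"n_disomic": len(disomic), "kw_H": kw.H, "kw_p": kw.p,
            "fold": fold.fold}


def stage_ase(cfg: RunConfig, indir: Path, outdir: Path) -> dict:
    sites = pd.read_csv(indir / "sites.tsv", sep="\t")
    site = sites.iloc[0]
    out = {}
    counts = {}
    for assay in ("assay", "input"):
        for tag in ("masked", "unmasked"):
            recs = rio.read_pileup_tsv(indir / f"pileup_{assay}_{tag}.tsv")
            c = AL.count_allelic_reads(recs, site["site"], site.chrom, int(site.pos),
                                       site.ref, site.alt, assay=assay)
            counts[(assay, tag)] = c
            out[f"alt_fraction_{assay}_{tag}"] = (c.k_alt / c.n) if c.n else np.nan
    paired = AL.paired_bias_assessment(counts[("assay", "masked")],
                                       counts[("input", "masked")],
                                       alpha=cfg.alpha)
    rows = [{"assay": a, "reference": t, "k_ref": c.k_ref, "k_alt": c.k_alt,
             "n": c.n, "p": AL.binomial_bias_test(c.k_alt, c.n).p}
            for (a, t), c in counts.items()]
    pd.DataFrame(rows).to_csv(outdir / "allelic_counts.tsv", sep="\t", index=False)
    out.update({"assay_p": paired.p, "input_p": paired.input_p,
                "allele_specific": paired.allele_specific})
    return out


def stage_chipq(cfg: RunConfig, indir: Path, outdir: Path) -> dict:
    cq = rio.read_cq_tsv(indir / "qpcr_cq.tsv")
    std = cq[cq.target == "standard"].sort_values("condition")
    quantities = np.array([100.0 / 5**j for j in range(len(std))])
    curve = Q.standard_curve_fit(quantities, std["cq"].to_numpy())

    locus = cq[cq.target == "locus"]
    q_of = {cond: np.array([Q.interpolate_quantity(curve, v)
                            for v in locus[locus.condition == cond]["cq"]])
            for cond in ("antibody", "igg", "input")}
    pct_ab = [Q.percent_input(ip, inp, 0.01)
              for ip, inp in zip(q_of["antibody"], q_of["input"])]
    pct_igg = [Q.percent_input(ip, inp, 0.01)
               for ip, inp in zip(q_of["igg"], q_of["input"])]
    fold = Q.fold_enrichment(float(np.mean(pct_ab)), float(np.mean(pct_igg)))
    t_p = Q.replicate_t_test(pct_ab, pct_igg)

    allele = cq[cq.target == "allele_A"].set_index("condition")["cq"]
    pref = Q.allele_preference_check(curve, allele["matched"], allele["mismatched"])
    pd.DataFrame([{"slope": curve.slope, "efficiency": curve.efficiency,
                   "pct_input_ab": np.mean(pct_ab), "pct_input_igg": np.mean(pct_igg),
                   "fold_enrichment": fold, "t_p": t_p,
                   "allele_preference": pref.preference}]).to_csv(
        outdir / "chip_qpcr.tsv", sep="\t", index=False)
    return {"curve_slope": curve.slope, "efficiency": curve.efficiency,
            "fold_enrichment": fold, "replicate_t_p": t_p,
            "allele_preference": pref.preference}


def stage_annotate(cfg: RunConfig, indir: Path, outdir: Path) -> dict:
    peaks = rio.read_bed(indir / "peaks.bed")
    tss = rio.read_tss_tsv(indir / "tss.tsv")
    assigned = AN.assign_peaks_to_tss(peaks, tss, window=cfg.tss_window)
    assigned.to_csv(outdir / "peak_tss_assignment.tsv", sep="\t", index=False)

    contacts, chrom, res = rio.read_contacts_tsv(indir / "contacts.tsv")
    tss0 = tss[0]
    link = AN.hic_link(contacts, peaks[0],
                       AN.GenomicInterval(chrom, tss0.position - 1, tss0.position),
                       res, cfg.hic_threshold)

    seq = rio.read_fasta(indir / "breakpoint_locus.fasta")["locus"]
    motif_hits = AN.motif_scan(seq, "TTGCGCAA", max_mismatches=0)
    return {"n_peaks": len(peaks), "n_tss_proximal_genes": assigned["gene"].nunique(),
            "hic_linked": link.linked, "hic_max_contact": link.max_contact,
            "n_motif_hits": len(motif_hits)}


def stage_programs(cfg: RunConfig, indir: Path, outdir: Path) -> dict:
    expr = rio.read_expression_tsv(indir / "cohort_expression.tsv")
    flags = pd.read_csv(indir / "sample_flags.tsv", sep="\t",
                        index_col="sample")["translocated"].astype(bool)
    cohort = expr.loc[:, ~flags.reindex(expr.columns).fillna(False)]

    corr = P.spearman_correlate(cohort, "DRIVER")
    corr.to_csv(outdir / "driver_correlation.tsv", sep="\t")
    corr_set = P.correlated_gene_set(corr, "DRIVER", cfg.corr_p)

    de = pd.read_csv(indir / "de_table.tsv", sep="\t")
    top = set(P.top_de_genes(de, k=cfg.top_k))
    universe = (set(expr.index) & set(de["gene"])) - {"DRIVER"}
    overlap = P.overlap_binomial(universe, corr_set & universe, top & universe)
    _dump_json(dataclasses.asdict(overlap), outdir / "overlap.json")

    z = P.translocation_zscore(expr, flags, "DRIVER")
    return {"n_correlated": len(corr_set), "overlap": overlap.overlap,
            "overlap_expected": overlap.expected, "overlap_p": overlap.p,
            "mean_translocation_z": z.mean_z}


def stage_breakpoints(cfg: RunConfig, indir: Path, outdir: Path) -> dict:
    seqs = rio.read_fasta(indir / "breakpoint_locus.fasta")
    bps = pd.read_csv(indir / "breakpoints.tsv", sep="\t")
    bp = bps.iloc[0]
    seq = seqs["locus"]
    down = B.extract_flank(seq, int(bp.position), "downstream", 200)
    hits = B.rss_scan(down.sequence)
    call = B.classify_breakpoint(hits, breakpoint_offset=0, window=50,
                                 name=str(bp["name"]))
    _dump_json([dataclasses.asdict(h) for h in hits], outdir / "rss_hits.json")
    return {"n_rss_hits": len(hits),
            "n_full_rss": sum(h.classification == "full-RSS" for h in hits),
            "breakpoint_category": call.category,
            "nearest_hit_bp": call.nearest_distance if call.nearest_distance != float("inf") else None}


_STAGE_FUNCS = {
    "assoc": stage_assoc, "eqtl": stage_eqtl, "ase": stage_ase,
    "chipq": stage_chipq, "annotate": stage_annotate,
    "programs": stage_programs, "breakpoints": stage_breakpoints,
}


def validate_inputs(indir: Path) -> dict:
    """Report-only validation of the input directory; never raises."""
    errors, warnings_ = [], []

    def check(fn, *args, label=""):
        try:
            fn(*args)
        except FileNotFoundError:
            warnings_.append(f"{label}: missing")
        except Exception as exc:  # format problems are fatal
            errors.append(f"{label}: {exc}")

    check(rio.read_genotype_tsv, indir / "genotypes.tsv", label="genotypes.tsv")
    check(rio.read_expression_tsv, indir / "cohort_expression.tsv",
          label="cohort_expression.tsv")
    check(rio.read_bed, indir / "peaks.bed", label="peaks.bed")
    check(rio.read_fasta, indir / "breakpoint_locus.fasta",
          label="breakpoint_locus.fasta")
    return {"errors": errors, "warnings": warnings_}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the selected stages in dependency order.

    Returns the summary dict; also writes ``summary.json``, a resolved
    config copy and a log file under ``cfg.outdir``.  A stage failure
    halts the run with a named error; earlier stages' outputs survive.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("regfine %s seed=%d stages=%s", __version__, cfg.seed, cfg.stages)

    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(cfg.resolved(), sort_keys=True))

    indir = outdir / "inputs"
    unknown = [s for s in cfg.stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")

    summary: dict = {"version": __version__, "seed": cfg.seed}
    try:
        if "simulate" in cfg.stages:
            if not cfg.simulate:
                raise ValueError("simulate stage requested without --simulate")
            t0 = time.perf_counter()
            summary["simulate"] = stage_simulate(cfg, indir)
            log.info("stage simulate done in %.2fs", time.perf_counter() - t0)
        elif not indir.exists():
            raise FileNotFoundError(
                f"input directory {indir} missing and simulate stage not selected")

        for stage in [s for s in cfg.stages if s != "simulate"]:
            stage_out = outdir / stage
            stage_out.mkdir(exist_ok=True)
            t0 = time.perf_counter()
            try:
                summary[stage] = _STAGE_FUNCS[stage](cfg, indir, stage_out)
            except Exception as exc:
                log.error("stage %s failed: %s", stage, exc)
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()

    _dump_json(summary, outdir / "summary.json")
    return summary
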