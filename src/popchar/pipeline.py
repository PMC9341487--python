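"""End-to-end characterization pipeline and report rendering.

``run_characterization`` drives every stage over either a synthetic
multi-breed scenario (default; fully determined by the config seed) or
user-supplied PLINK filesets: QC -> MAF spectrum -> GRM/PCA -> Reynolds
distances/NJ tree -> inbreeding (pedigree + genomic + F_ROH) -> LD decay and
Ne -> gametic-phase consistency per founder -> ROH/HER and islands.  Every
table is written as TSV into the output directory together with a JSON
manifest of parameters and seeds.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import (
    GenotypePanel,
    QCParams,
    allele_frequencies,
    maf_spectrum,
    merge_panels,
    qc_filter,
    read_panel,
    write_panel,
)
from .ld_ne_phase import LDBinScheme, gametic_phase_consistency, ld_decay, ne_from_ld
from .pedigree_metrics import (
    build_pedigree,
    breed_composition,
    cohort_deltaF,
    equivalent_generations,
    ne_from_deltaF,
    wright_inbreeding,
)
from .population_structure import distance_matrix, neighbor_joining, supervised_admixture
from .relatedness_inbreeding import build_grm, inbreeding_correlations, inbreeding_table, pca
from .roh_her import HERParams, ROHParams, call_islands, classify_segments, detect_her, detect_roh, f_roh
from .synthetic_data import CrossingScheme, FounderModel, simulate_composite_cross, simulate_founder_panels

DEFAULT_BREED_FST = {"ANG": 0.10, "CAR": 0.12, "CAN": 0.10, "CHL": 0.10, "NEL": 0.25}


@dataclass
class RunConfig:
    """Declarative configuration of a characterization run."""

    out_dir: str = "popchar_run"
    seed: int = 42
    # synthetic scenario (used when input_prefixes is empty)
    n_snps: int = 3000
    n_individuals_per_breed: int = 50
    n_offspring: int = 100
    breed_fst: dict = field(default_factory=lambda: dict(DEFAULT_BREED_FST))
    chrom_lengths_bp: list = field(
        default_factory=lambda: [120_000_000, 100_000_000, 80_000_000]
    )
    ld_decay_bp: float = 100_000.0
    cM_per_Mb: float = 1.0
    # real-data inputs: population label -> PLINK prefix (bed) ; optional pedigree TSV
    input_prefixes: dict = field(default_factory=dict)
    composite_population: str = "COMPOSITE"
    pedigree_path: str | None = None
    # analysis parameters
    qc: QCParams = field(default_factory=QCParams)
    roh: ROHParams = field(default_factory=ROHParams)
    her: HERParams = field(default_factory=HERParams)
    roh_island_incidence: float = 0.36
    her_island_incidence: float = 0.10
    ne_alpha: int = 1
    pca_components: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, klass in (("qc", QCParams), ("roh", ROHParams), ("her", HERParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _log(stage: str) -> None:
    sys.stderr.write(f"[popchar] {stage}\n")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_characterization(config: RunConfig) -> dict:
    """Execute every stage; returns the in-memory bundle (also written as TSV)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    def stage(name):
        def deco(fn):
            _log(name)
            try:
                fn()
            except Exception as e:  # noqa: BLE001 - abort with stage name
                raise StageError(name, e) from e

        return deco

    panels: dict[str, GenotypePanel] = {}
    pedigree_df = None
    fractions = None

    @stage("inputs")
    def _inputs():
        nonlocal pedigree_df, fractions
        if config.input_prefixes:
            for popname, prefix in config.input_prefixes.items():
                if not Path(str(prefix) + ".bed").exists():
                    raise FileNotFoundError(f"population {popname}: missing fileset {prefix}")
                panels[popname] = read_panel(prefix, format="bed")
            if config.pedigree_path:
                pedigree_df = pd.read_csv(config.pedigree_path, sep="\t", dtype=str)
        else:
            breeds = sorted(config.breed_fst)
            model = FounderModel(
                n_breeds=len(breeds),
                fst=[config.breed_fst[b] for b in breeds],
                n_snps=config.n_snps,
                chrom_lengths_bp=list(config.chrom_lengths_bp),
                ld_decay_bp=config.ld_decay_bp,
                n_individuals=config.n_individuals_per_breed,
                breed_names=breeds,
                seed=config.seed,
            )
            founders = simulate_founder_panels(model)
            scheme = CrossingScheme()
            composite, ped, fr = simulate_composite_cross(
                founders, scheme, n_offspring=config.n_offspring,
                cM_per_Mb=config.cM_per_Mb, seed=config.seed + 1,
            )
            panels.update(founders)
            panels[config.composite_population] = composite
            pedigree_df, fractions = ped, fr
            ped.to_csv(out / "pedigree.tsv", sep="\t", index=False)
            fr.to_csv(out / "true_breed_fractions.tsv", sep="\t")
            for name, p in panels.items():
                write_panel(p, out / "genotypes" / name, format="bed")

    comp = config.composite_population

    @stage("qc")
    def _qc():
        merged = merge_panels([panels[k] for k in sorted(panels)])
        qc_panel, report = qc_filter(merged, config.qc)
        rohqc = QCParams(
            min_call_rate=config.qc.min_call_rate,
            min_maf=config.qc.min_maf,
            hwe_p_floor=config.qc.hwe_p_floor,
            apply_maf_hwe=False,
        )
        comp_only = panels[comp]
        comp_rohqc, _ = qc_filter(comp_only, rohqc)
        comp_qc, _ = qc_filter(comp_only, config.qc)
        bundle["qc_panel"] = qc_panel
        bundle["roh_panel"] = comp_rohqc
        bundle["comp_panel"] = comp_qc
        report.as_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        bundle["qc_report"] = report

    def _by_pop(panel: GenotypePanel) -> dict[str, GenotypePanel]:
        pops = {}
        for popname in panel.samples["population"].unique():
            idx = np.nonzero((panel.samples["population"] == popname).to_numpy())[0]
            pops[popname] = GenotypePanel(
                panel.variants, panel.samples.iloc[idx], panel.dosages[idx]
            )
        return pops

    @stage("maf_spectrum")
    def _maf():
        spec = maf_spectrum(bundle["comp_panel"])
        spec.to_csv(out / "maf_spectrum.tsv", sep="\t", index=False)
        bundle["maf_spectrum"] = spec

    @stage("grm_pca")
    def _grm():
        qc_panel = bundle["qc_panel"]
        grm = build_grm(qc_panel)
        scores, varexp = pca(grm, k=min(config.pca_components, qc_panel.n_individuals))
        sc = pd.DataFrame(
            scores,
            index=qc_panel.samples["iid"],
            columns=[f"PC{i+1}" for i in range(scores.shape[1])],
        )
        sc.insert(0, "population", qc_panel.samples["population"].to_numpy())
        sc.to_csv(out / "pca_scores.tsv", sep="\t")
        pd.DataFrame({"PC": sc.columns[1:], "variance_explained": varexp}).to_csv(
            out / "pca_varexp.tsv", sep="\t", index=False
        )
        bundle["grm"], bundle["pca_scores"], bundle["pca_varexp"] = grm, sc, varexp

    @stage("distances_tree")
    def _tree():
        pops = _by_pop(bundle["qc_panel"])
        D = distance_matrix(pops)
        tree = neighbor_joining(D)
        D.to_csv(out / "distance_matrix.tsv", sep="\t")
        (out / "tree.nwk").write_text(tree.newick + "\n")
        bundle["distances"], bundle["tree"] = D, tree

    @stage("admixture")
    def _admix():
        pops = _by_pop(bundle["qc_panel"])
        founder_names = [p for p in sorted(pops) if p != comp]
        F = pd.DataFrame(
            {name: allele_frequencies(pops[name]) for name in founder_names}
        ).T
        est = supervised_admixture(pops[comp], F)
        est.Q.to_csv(out / "admixture_Q.tsv", sep="\t")
        bundle["admixture_Q"] = est.Q

    @stage("roh_her")
    def _rohher():
        roh_panel = bundle["roh_panel"]
        roh = detect_roh(roh_panel, config.roh)
        her = detect_her(roh_panel, config.her)
        roh.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        her.to_csv(out / "her_segments.tsv", sep="\t", index=False)
        classify_segments(roh, "ROH").to_csv(out / "roh_classes.tsv", sep="\t", index=False)
        classify_segments(her, "HER").to_csv(out / "her_classes.tsv", sep="\t", index=False)
        roh_isl = call_islands(roh, roh_panel, config.roh_island_incidence)
        her_isl = call_islands(her, roh_panel, config.her_island_incidence)
        roh_isl.to_csv(out / "roh_islands.tsv", sep="\t", index=False)
        her_isl.to_csv(out / "her_islands.tsv", sep="\t", index=False)
        bundle["roh"], bundle["her"] = roh, her
        bundle["roh_islands"], bundle["her_islands"] = roh_isl, her_isl

    @stage("inbreeding")
    def _inbreeding():
        table = inbreeding_table(bundle["comp_panel"])
        froh = f_roh(bundle["roh"], bundle["roh_panel"])
        table = table.join(froh, how="left").fillna(0.0)
        if pedigree_df is not None:
            ped = build_pedigree(pedigree_df)
            fped = wright_inbreeding(ped)
            table.insert(0, "F_PED", fped.reindex(table.index).fillna(0.0))
            bundle["pedigree"] = ped
            bundle["equiv_generations"] = equivalent_generations(ped)
        table.index.name = "iid"
        table.to_csv(out / "inbreeding_table.tsv", sep="\t")
        corr = inbreeding_correlations(table)
        corr.to_csv(out / "inbreeding_correlations.tsv", sep="\t")
        bundle["inbreeding_table"], bundle["inbreeding_correlations"] = table, corr

    @stage("ld_ne")
    def _ld():
        comp_qc = bundle["comp_panel"]
        scheme = LDBinScheme()
        bins, overall = ld_decay(comp_qc, scheme, seed=config.seed)
        bins.to_csv(out / "ld_bins.tsv", sep="\t", index=False)
        ne = ne_from_ld(bins, alpha=config.ne_alpha, cM_per_Mb=config.cM_per_Mb,
                        sample_n=comp_qc.n_individuals)
        ne.to_csv(out / "ne_ld.tsv", sep="\t", index=False)
        bundle["ld_bins"], bundle["ld_overall"], bundle["ne_ld"] = bins, overall, ne
        if "pedigree" in bundle:
            try:
                series = cohort_deltaF(bundle["pedigree"], cohort_by="birth_year")
                series.to_csv(out / "cohort_deltaF.tsv", sep="\t", index=False)
                dF = series["delta_F"].dropna()
                last = float(dF.iloc[-1]) if len(dF) else np.nan
                bundle["ne_pedigree"] = ne_from_deltaF(last) if last > 0 else np.nan
                bundle["cohort_deltaF"] = series
            except Exception:
                bundle["ne_pedigree"] = np.nan

    @stage("cgp")
    def _cgp():
        pops = _by_pop(bundle["qc_panel"])
        scheme = LDBinScheme()
        cgp = {}
        for popname in sorted(pops):
            if popname == comp:
                continue
            tab = gametic_phase_consistency(pops[comp], pops[popname], scheme,
                                            seed=config.seed)
            tab.to_csv(out / f"cgp_{popname}.tsv", sep="\t", index=False)
            cgp[popname] = tab
        bundle["cgp"] = cgp

    @stage("manifest")
    def _manifest():
        manifest = {
            "popchar_version": __version__,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "populations": sorted(panels),
            "n_snps_after_qc": int(bundle["qc_panel"].n_snps),
            "ld_overall": bundle["ld_overall"],
            "n_roh": int(len(bundle["roh"])),
            "n_her": int(len(bundle["her"])),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        bundle["manifest"] = manifest

    bundle["out_dir"] = str(out)
    if fractions is not None:
        bundle["true_fractions"] = fractions
    return bundle


def make_report(bundle: dict) -> str:
    """Human-readable summary of a characterization bundle.

    Renders the inbreeding summary, the CGP grid, the island lists and the
    segment-length histograms; a partial bundle produces a partial report
    with warnings rather than an error.
    """
    lines: list[str] = ["# Composite-breed characterization report", ""]
    warn: list[str] = []

    tab = bundle.get("inbreeding_table")
    if tab is not None:
        lines.append("## Inbreeding coefficients")
        desc = tab.describe().loc[["count", "mean", "std", "min", "max"]].T
        lines.append(desc.to_string(float_format=lambda x: f"{x:.4f}"))
        lines.append("")
    else:
        warn.append("inbreeding table missing")

    cgp = bundle.get("cgp")
    if cgp:
        lines.append("## Consistency of gametic phase (per distance bin)")
        grid = None
        for popname, tabp in cgp.items():
            col = tabp.loc[tabp["reported"], ["bin_high_bp", "correlation"]].set_index(
                "bin_high_bp"
            )["correlation"].rename(popname)
            grid = col.to_frame() if grid is None else grid.join(col, how="outer")
        if grid is not None:
            grid.index = [f"{int(x)//1000}kb" for x in grid.index]
            lines.append(grid.to_string(float_format=lambda x: f"{x:.2f}"))
        lines.append("")
    else:
        warn.append("CGP tables missing")

    for kind in ("roh", "her"):
        segs = bundle.get(kind)
        if segs is None:
            warn.append(f"{kind.upper()} segments missing")
            continue
        lines.append(f"## {kind.upper()}: {len(segs)} segments")
        if len(segs):
            lines.append(classify_segments(segs, kind.upper()).to_string(index=False))
        isl = bundle.get(f"{kind}_islands")
        if isl is not None:
            lines.append(f"{kind.upper()} islands: {len(isl)}")
            if len(isl):
                lines.append(isl.to_string(index=False))
        lines.append("")

    ld = bundle.get("ld_overall")
    if ld:
        lines.append(
            f"## LD: mean r2 = {ld['mean_r2']:.4f} (sd {ld['sd_r2']:.4f}, "
            f"{ld['n_pairs']} pairs)"
        )
    ne = bundle.get("ne_ld")
    if ne is not None and len(ne):
        lines.append(f"Ne (LD, oldest bin): {ne['Ne'].iloc[0]:.0f} at T="
                     f"{ne['T_generations'].iloc[0]:.0f} generations")
    if not np.isnan(bundle.get("ne_pedigree", np.nan)):
        lines.append(f"Ne (pedigree): {bundle['ne_pedigree']:.0f}")
    lines.append("")
    if warn:
        lines.append("WARNINGS: " + "; ".join(warn))
    return "\n".join(lines)
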