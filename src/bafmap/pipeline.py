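"""End-to-end orchestration over all analysis stages.

A :class:`RunConfig` names the stages to run, the parameters, and the
output directory; :func:`run` executes the stages in dependency order
(simulate → classify → cooccupy/state-enrich → chiprx/invade →
integrate-expression; screen, qpcr and bioid are independent).  Every run
writes a ``manifest.json`` capturing the configuration, package version
and SHA-256 checksums of the files it consumed, and appends structured
JSON-lines logs at stage boundaries.  Outputs are written only under the
run directory and inputs are never mutated; a re-run with identical
configuration produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .intervals import (
    PeakSet,
    read_chrom_sizes,
    read_peaks,
    read_segmentation,
    write_peaks,
)
from .chiprx import (
    invasion_analysis,
    quartile_stratify,
    read_spikein_counts,
    rpmpr_normalize,
    rrpm_normalize,
    signal_delta_track,
    write_spikein_counts,
)
from .proteomics import bioid_enrichment, read_intensity_matrix
from .qpcr import relative_expression
from .screen import fold_depletion, normalize_depth, read_screen_counts, specificity_rank
from .simulate import (
    CRTF_FACTORS,
    SimulationConfig,
    simulate_chiprx,
    simulate_peaksets,
    simulate_proteomics,
    simulate_qpcr,
    simulate_screen,
)
from .subcomplexes import (
    CLASS_LABELS,
    classify_subcomplexes,
    cooccupancy_fractions,
    assign_peaks_to_genes,
    expression_by_occupancy,
    read_deg_table,
    read_tss_table,
    state_enrichment,
)

ALL_STAGES = (
    "simulate",
    "classify",
    "cooccupy",
    "state-enrich",
    "chiprx",
    "invade",
    "integrate-expression",
    "screen",
    "qpcr",
    "bioid",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parameters and stage selection for one pipeline run."""

    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    min_bp: int = 1
    pseudocount: float = 0.5
    screen_pseudocount: float = 1.0
    window_bp: int = 50_000
    bootstrap_b: int = 2000
    fc_threshold: float = 2.5
    p_threshold: float = 0.05
    invasion_effect: float = 1.0
    sim: SimulationConfig | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)
            # default run exercises the all-missing-control pseudo-FC path
            self.sim.proteomics.n_forced_missing_control = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "sim" in raw and isinstance(raw["sim"], dict):
            raw["sim"] = SimulationConfig(**raw["sim"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.log_path = self.out / "run.log"
        self.inputs_seen: dict[str, str] = {}
        self._log_lines: list[str] = []

    def log(self, stage: str, event: str, **extra) -> None:
        rec = {"stage": stage, "event": event, **extra}
        self._log_lines.append(json.dumps(rec, sort_keys=True))

    def path(self, *parts: str) -> Path:
        p = self.out.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    def read_input(self, *parts: str) -> Path:
        p = self.out.joinpath(*parts)
        if not p.exists():
            raise FileNotFoundError(
                f"required input {p} missing; run its producing stage first"
            )
        self.inputs_seen[str(p.relative_to(self.out))] = _sha256(p)
        return p

    def finish(self) -> None:
        with open(self.log_path, "w") as fh:
            fh.write("\n".join(self._log_lines) + "\n")
        manifest = {
            "package_version": __version__,
            "config": _config_dict(self.cfg),
            "input_checksums": dict(sorted(self.inputs_seen.items())),
            "stages_run": list(self.cfg.stages),
        }
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["stages"] = list(d["stages"])
    return d


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(r: _Run) -> None:
    cfg = r.cfg
    sim = cfg.sim
    peaksets, truth = simulate_peaksets(sim)
    for factor, ps in peaksets.items():
        write_peaks(ps, r.path("simulated", f"{factor}.narrowPeak"), "narrowPeak")
    truth.to_csv(r.path("simulated", "site_truth.tsv"), sep="\t")

    # chromatin-state segmentation derived from the planted classes:
    # PBAF-containing sites behave promoter-like, the rest enhancer-like
    with open(r.path("simulated", "genome.chrom.sizes"), "w") as fh:
        for chrom in sorted(sim.genome):
            fh.write(f"{chrom}\t{sim.genome[chrom]}\n")
    seg_rows = []
    for sid, row in truth.iterrows():
        if row["class_label"] == "BRG1_unassigned":
            state = "weak"
        elif row["has_pbrm1"]:
            state = "promoter_active"
        else:
            state = "enhancer"
        seg_rows.append((row["chrom"], int(row["start"]), int(row["end"]), state))
    by_chrom: dict[str, list[tuple[int, int, str]]] = {c: [] for c in sim.genome}
    for chrom, s, e, st in seg_rows:
        by_chrom[chrom].append((s, e, st))
    with open(r.path("simulated", "segmentation.bed"), "w") as fh:
        for chrom in sorted(by_chrom):
            pos = 0
            for s, e, st in sorted(by_chrom[chrom]):
                if s > pos:
                    fh.write(f"{chrom}\t{pos}\t{s}\tquiescent\n")
                fh.write(f"{chrom}\t{s}\t{e}\t{st}\n")
                pos = e
            if pos < sim.genome[chrom]:
                fh.write(f"{chrom}\t{pos}\t{sim.genome[chrom]}\tquiescent\n")

    # TSS table + differential-expression truth: one gene per site, BAF-only
    # bound genes respond to ATPase loss
    rng = np.random.default_rng([sim.seed, 6])
    tss_rows, deg_rows = [], []
    for i, (sid, row) in enumerate(truth.iterrows()):
        gene = f"GENE{i:05d}"
        tss = int(row["end"]) + 5000
        shift = 0.8 if (row["class_label"] == "BAF_only" and row["MYCN"]) else 0.0
        deg_rows.append((gene, float(rng.normal(shift, 1.0))))
        tss_rows.append((gene, row["chrom"], tss + 1, "+"))
    with open(r.path("simulated", "tss.tsv"), "w") as fh:
        fh.write("gene\tchrom\ttss_position\tstrand\n")
        for g, c, p, s in tss_rows:
            fh.write(f"{g}\t{c}\t{p}\t{s}\n")
    pd.DataFrame(deg_rows, columns=["gene", "log2fc"]).to_csv(
        r.path("simulated", "deg.tsv"), sep="\t", index=False
    )

    # spike-in libraries: MYCN gains at BRG1∩MYCN co-occupied sites after
    # ATPase loss; the ATPase library itself collapses
    brg1 = peaksets["BRG1"]
    co_sites = [f"BRG1_{sid}" for sid, row in truth.iterrows() if row["MYCN"]]
    effects_mycn = {s: cfg.invasion_effect for s in co_sites}
    libs, chip_truth = simulate_chiprx(
        sim, brg1, {"control_MYCN": 0.0, "treated_MYCN": effects_mycn}
    )
    libs_brg1, _ = simulate_chiprx(
        sim, brg1, {"control_BRG1": 0.0, "treated_BRG1": -3.32}
    )
    for cond, lib in {**libs, **libs_brg1}.items():
        write_spikein_counts(lib, r.path("simulated", f"chiprx_{cond}.tsv"))
    chip_truth.to_csv(r.path("simulated", "chiprx_truth.tsv"), sep="\t")
    with open(r.path("simulated", "co_occupied_sites.txt"), "w") as fh:
        fh.write("\n".join(co_sites) + "\n")

    screen_counts, screen_truth = simulate_screen(sim)
    sc_df = screen_counts.guides.join(screen_counts.counts)
    sc_df.index.name = "guide"
    sc_df.to_csv(r.path("simulated", "screen_counts.tsv"), sep="\t")
    screen_counts.samples.to_csv(r.path("simulated", "screen_samples.tsv"), sep="\t")
    screen_truth.to_csv(r.path("simulated", "screen_truth.tsv"), sep="\t")

    fold_changes = {
        "MYL1": {"sgBRG1": 4.0},
        "MYH3": {"sgBRG1": 8.0},
        "CKM": {"sgBRG1": 6.0},
        "TNNT3": {"sgBRG1": 3.0},
        "MYCN": {"sgBRG1": 1.0},
    }
    ct_table, qpcr_truth = simulate_qpcr(sim, fold_changes, control_condition="sgScr")
    ct_table.to_csv(r.path("simulated", "qpcr_ct.tsv"), sep="\t", index=False)
    qpcr_truth.to_csv(r.path("simulated", "qpcr_truth.tsv"), sep="\t", index=False)

    m, prot_truth = simulate_proteomics(sim)
    out = m.intensities.copy()
    out.insert(0, "n_peptides", m.n_peptides)
    out.index.name = "protein"
    out.to_csv(r.path("simulated", "bioid_intensities.tsv"), sep="\t")
    m.groups.rename("condition").to_frame().rename_axis("sample").to_csv(
        r.path("simulated", "bioid_groups.tsv"), sep="\t"
    )
    prot_truth.to_csv(r.path("simulated", "bioid_truth.tsv"), sep="\t")
    r.log("simulate", "done", n_sites=len(truth))


def _load_peaksets(r: _Run) -> dict[str, PeakSet]:
    out = {}
    for factor in ("BRG1", "DPF2", "PBRM1", "BRD9", *CRTF_FACTORS):
        p = r.read_input("simulated", f"{factor}.narrowPeak")
        out[factor] = read_peaks(p, "narrowPeak", factor=factor)
    return out


def _stage_classify(r: _Run) -> None:
    ps = _load_peaksets(r)
    calls = classify_subcomplexes(
        ps["BRG1"], ps["DPF2"], ps["PBRM1"], ps["BRD9"], r.cfg.min_bp
    )
    calls.table.to_csv(r.path("classify", "subcomplex_calls.tsv"), sep="\t")
    calls.class_counts().rename("n_sites").to_frame().rename_axis("class_label").to_csv(
        r.path("classify", "class_counts.tsv"), sep="\t"
    )
    for label in CLASS_LABELS:
        members = calls.class_members(label)
        if members:
            write_peaks(
                PeakSet(label, members),
                r.path("classify", f"sites_{label.replace('+', '_')}.bed"),
                "bed",
            )
    if calls.pbrm1_without_brg1 is not None:
        write_peaks(
            calls.pbrm1_without_brg1, r.path("classify", "PBRM1_without_BRG1.bed"), "bed"
        )
    r.log("classify", "done", n_brg1=len(calls))


def _get_calls(r: _Run):
    ps = _load_peaksets(r)
    return ps, classify_subcomplexes(
        ps["BRG1"], ps["DPF2"], ps["PBRM1"], ps["BRD9"], r.cfg.min_bp
    )


def _stage_cooccupy(r: _Run) -> None:
    ps, calls = _get_calls(r)
    tab = cooccupancy_fractions(calls, [ps[f] for f in CRTF_FACTORS], r.cfg.min_bp)
    tab.fractions.rename_axis("class_label").to_csv(
        r.path("cooccupy", "cooccupancy_fractions.tsv"), sep="\t"
    )
    tab.counts.rename_axis("class_label").to_csv(
        r.path("cooccupy", "cooccupancy_counts.tsv"), sep="\t"
    )
    tab.reverse_fractions.rename_axis("factor").to_csv(
        r.path("cooccupy", "crtf_share_by_class.tsv"), sep="\t"
    )
    r.log("cooccupy", "done")


def _stage_state_enrich(r: _Run) -> None:
    ps, calls = _get_calls(r)
    sizes = read_chrom_sizes(r.read_input("simulated", "genome.chrom.sizes"))
    seg = read_segmentation(r.read_input("simulated", "segmentation.bed"), sizes)
    categories: dict[str, PeakSet] = {}
    brg1_names = calls.table
    pbrm1_alone = calls.pbrm1_without_brg1
    if pbrm1_alone is not None:
        categories["PBRM1_alone"] = pbrm1_alone
    with_p = brg1_names.index[brg1_names["has_pbrm1"]]
    without_p = brg1_names.index[~brg1_names["has_pbrm1"]]
    by_name = calls.brg1.by_name()
    if len(with_p):
        categories["PBRM1+BRG1"] = PeakSet("PBRM1+BRG1", [by_name[n] for n in with_p])
    if len(without_p):
        categories["BRG1_alone"] = PeakSet("BRG1_alone", [by_name[n] for n in without_p])
    for f in CRTF_FACTORS:
        categories[f] = ps[f]
    cols = {}
    for name, cps in categories.items():
        cols[name] = state_enrichment(cps, seg)
    table = pd.DataFrame(cols).rename_axis("state")
    table.to_csv(r.path("state_enrich", "state_enrichment.tsv"), sep="\t")
    r.log("state-enrich", "done", categories=sorted(categories))


def _stage_chiprx(r: _Run) -> None:
    control = read_spikein_counts(r.read_input("simulated", "chiprx_control_MYCN.tsv"))
    treated = read_spikein_counts(r.read_input("simulated", "chiprx_treated_MYCN.tsv"))
    union = list(control.counts.index)
    for name, lib in (("control_MYCN", control), ("treated_MYCN", treated)):
        pd.DataFrame(
            {"rrpm": rrpm_normalize(lib), "rpmpr": rpmpr_normalize(lib, union)}
        ).rename_axis("peak").to_csv(r.path("chiprx", f"normalized_{name}.tsv"), sep="\t")
    anchor = rpmpr_normalize(control, union)
    partner_lib = read_spikein_counts(r.read_input("simulated", "chiprx_control_BRG1.tsv"))
    partner = rpmpr_normalize(partner_lib, union)
    q = quartile_stratify(anchor, partner)
    q.to_csv(r.path("chiprx", "quartile_stratification.tsv"), sep="\t")
    r.log("chiprx", "done")


def _stage_invade(r: _Run) -> None:
    control = read_spikein_counts(r.read_input("simulated", "chiprx_control_MYCN.tsv"))
    treated = read_spikein_counts(r.read_input("simulated", "chiprx_treated_MYCN.tsv"))
    sites = (
        r.read_input("simulated", "co_occupied_sites.txt").read_text().split()
    )
    res = invasion_analysis(sites, control, treated, r.cfg.pseudocount)
    res.deltas.rename_axis("site").to_frame().to_csv(
        r.path("invade", "invasion_deltas.tsv"), sep="\t"
    )
    pd.DataFrame(
        [
            {
                "n_sites": res.n_sites,
                "median_delta": res.median_delta,
                "fraction_increased": res.fraction_increased,
                "p_value": res.p_value,
            }
        ]
    ).to_csv(r.path("invade", "invasion_summary.tsv"), sep="\t", index=False)
    ctrl_b = read_spikein_counts(r.read_input("simulated", "chiprx_control_BRG1.tsv"))
    trt_b = read_spikein_counts(r.read_input("simulated", "chiprx_treated_BRG1.tsv"))
    track = signal_delta_track(ctrl_b, trt_b, list(ctrl_b.counts.index), r.cfg.pseudocount)
    track.rename_axis("peak").to_csv(r.path("invade", "brg1_delta_track.tsv"), sep="\t")
    r.log("invade", "done", n_sites=res.n_sites)


def _stage_integrate_expression(r: _Run) -> None:
    ps, calls = _get_calls(r)
    tss = read_tss_table(r.read_input("simulated", "tss.tsv"))
    deg = read_deg_table(r.read_input("simulated", "deg.tsv"))
    assignments = assign_peaks_to_genes(ps["BRG1"], tss, r.cfg.window_bp, calls)
    # BRG1-bound genes split by MYCN co-occupancy of their assigned peaks
    from .intervals import intersect_sets

    mycn_overlap = intersect_sets(ps["BRG1"], ps["MYCN"], r.cfg.min_bp)
    groups: dict[str, list[str]] = {"BRG1_only": [], "BRG1+MYCN": []}
    for a in assignments:
        has_mycn = any(mycn_overlap[p] for p in a.assigned_peaks)
        groups["BRG1+MYCN" if has_mycn else "BRG1_only"].append(a.gene)
    summary = expression_by_occupancy(
        deg, groups, n_boot=r.cfg.bootstrap_b, seed=np.random.default_rng([r.cfg.seed, 7])
    )
    summary.to_csv(r.path("integrate_expression", "expression_by_occupancy.tsv"), sep="\t")
    r.log("integrate-expression", "done", groups={k: len(v) for k, v in groups.items()})


def _stage_screen(r: _Run) -> None:
    sc = read_screen_counts(
        r.read_input("simulated", "screen_counts.tsv"),
        r.read_input("simulated", "screen_samples.tsv"),
    )
    norm = normalize_depth(sc.counts)
    lfc = fold_depletion(norm, sc.samples, r.cfg.screen_pseudocount)
    table = specificity_rank(lfc, sc.guides, sc.samples)
    table.targets.rename_axis("target_domain").to_csv(
        r.path("screen", "screen_ranked.tsv"), sep="\t"
    )
    table.control_null.rename("specificity").rename_axis("guide").to_frame().to_csv(
        r.path("screen", "control_null.tsv"), sep="\t"
    )
    r.log("screen", "done", n_targets=len(table.targets))


def _stage_qpcr(r: _Run) -> None:
    ct = pd.read_csv(r.read_input("simulated", "qpcr_ct.tsv"), sep="\t")
    res = relative_expression(ct, control_condition="sgScr")
    res.to_csv(r.path("qpcr", "relative_expression.tsv"), sep="\t", index=False)
    r.log("qpcr", "done", n_assays=res["target"].nunique())


def _stage_bioid(r: _Run) -> None:
    m = read_intensity_matrix(
        r.read_input("simulated", "bioid_intensities.tsv"),
        r.read_input("simulated", "bioid_groups.tsv"),
    )
    res = bioid_enrichment(
        m, "bait", "control",
        fc_threshold=r.cfg.fc_threshold, p_threshold=r.cfg.p_threshold,
    )
    res.rename_axis("protein").to_csv(r.path("bioid", "bioid_enrichment.tsv"), sep="\t")
    r.log("bioid", "done", n_hits=int(res["hit"].sum()))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "cooccupy": _stage_cooccupy,
    "state-enrich": _stage_state_enrich,
    "chiprx": _stage_chiprx,
    "invade": _stage_invade,
    "integrate-expression": _stage_integrate_expression,
    "screen": _stage_screen,
    "qpcr": _stage_qpcr,
    "bioid": _stage_bioid,
}


def run(cfg: RunConfig) -> Path:
    """Execute the configured stages in dependency order.

    Returns the run directory.  The first failing stage aborts the run
    with :class:`StageError` naming it.  An empty stage list is a no-op
    that still writes a manifest.
    """
    r = _Run(cfg)
    ordered = [s for s in ALL_STAGES if s in cfg.stages]
    for stage in ordered:
        r.log(stage, "start")
        try:
            _STAGE_FUNCS[stage](r)
        except Exception as exc:  # noqa: BLE001 — abort naming the stage
            r.log(stage, "failed", error=str(exc))
            r.finish()
            raise StageError(stage, exc) from exc
    r.finish()
    return r.out
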