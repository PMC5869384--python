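"""Pipeline orchestration: simulate -> extract ORFs -> annotate (three
database tiers) -> expression filter -> family trees -> evaluate.

The library-level entry point is :func:`run_synthetic`, which executes the
whole audit in memory and returns every intermediate; :func:`run_pipeline`
wraps it with artifact writing for the CLI, and :func:`validate_config`
normalizes declarative YAML run configurations.
"""

from __future__ import annotations

import difflib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import pandas as pd
import yaml

from . import evaluation, expression, homology, phylo, sequence, simulate
from .expression import FilterParams
from .scoring import DEFAULT_SCHEME, ScoringScheme
from .simulate import SimulationConfig, SyntheticDataset

log = logging.getLogger("toxannot")

TIER_ORDER = ("species", "lineage", "distant")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs: dict | None = None  # paths: contigs, counts, proteome, databases{tier}
    filter_params: FilterParams = field(default_factory=FilterParams)
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    e_threshold: float = homology.DEFAULT_EVALUE
    d_max: float | str = "median"
    cluster_thresholds: tuple[float, ...] = (0.95, 0.90)
    sp_mode: str = "truth"
    out_dir: str = "toxannot_out"

    def __post_init__(self) -> None:
        if self.simulation is not None and self.inputs is not None:
            raise ValueError("provide either real inputs or a simulation, not both")
        if self.simulation is None and self.inputs is None:
            self.simulation = SimulationConfig(seed=self.seed)


@dataclass
class RunResult:
    dataset: SyntheticDataset | None
    cds_list: list
    annotations: dict[str, homology.AnnotationResult]
    predicted_contigs: dict[str, set[str]]
    expression: pd.DataFrame
    proteome_ids: set[str]
    filtered_ids: set[str]
    filtered_contigs: dict[str, set[str]]
    trees: dict[str, object]
    retained: dict[str, set[str]]
    report: dict


def _pr_or_none(predicted: set[str], truth: set[str]) -> dict[str, float | None]:
    if not predicted:
        return {"precision": None, "recall": None, "f1": None}
    p, r, f = evaluation.precision_recall(predicted, truth)
    return {"precision": p, "recall": r, "f1": f}


def _fpr_or_none(predicted: set[str], proteome: set[str]) -> float | None:
    return evaluation.false_positive_rate(predicted, proteome) if predicted else None


def run_synthetic(
    config: SimulationConfig | None = None,
    filter_params: FilterParams | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    e_threshold: float = homology.DEFAULT_EVALUE,
    d_max: float | str = "median",
    cluster_thresholds=(0.95, 0.90),
    sp_mode: str = "truth",
) -> RunResult:
    """Full audit on one synthetic dataset; everything stays in memory."""
    config = config or SimulationConfig()
    filter_params = filter_params or FilterParams()
    ds = simulate.simulate_dataset(config)
    return _analyse(ds, filter_params, scheme, e_threshold, d_max,
                    cluster_thresholds, sp_mode)


def _analyse(ds, filter_params, scheme, e_threshold, d_max,
             cluster_thresholds, sp_mode) -> RunResult:
    # 1. ORF extraction
    cds_list = []
    for cid in sorted(ds.contigs):
        cds_list.extend(sequence.extract_orfs(cid, ds.contigs[cid]))
    log.info("extracted %d candidate CDSs from %d contigs", len(cds_list), len(ds.contigs))

    # 2. homology annotation per database tier
    sp_labels = ds.sp_truth_labels if sp_mode == "truth" else None
    annotations: dict[str, homology.AnnotationResult] = {}
    predicted_contigs: dict[str, set[str]] = {}
    for tier in TIER_ORDER:
        db = ds.databases[tier]
        if not db:
            raise RuntimeError(f"homology stage failed: empty database tier {tier!r}")
        res = homology.annotate_dataset(
            cds_list, db, scheme, e_threshold, sp_mode, sp_labels)
        annotations[tier] = res
        predicted_contigs[tier] = {c.contig_id for c in res.survivors}
        log.info("tier %s: %s", tier, res.stage_counts)

    # 3. expression and the comparative filter
    expr = expression.expression_table(ds.counts, filter_params)
    filtered_ids = expression.expression_filter(expr, filter_params)
    filtered_contigs = {t: predicted_contigs[t] & filtered_ids for t in TIER_ORDER}

    # 4. family trees and clade-evidence retention
    family_members: dict[str, dict[str, str]] = {}
    cds_contig: dict[str, str] = {}
    for tier in TIER_ORDER:
        for assign, cds in zip(annotations[tier].assignments, annotations[tier].survivors):
            fam = assign.family
            if cds.id not in cds_contig:
                cds_contig[cds.id] = cds.contig_id
                family_members.setdefault(fam, {})[cds.id] = cds.mature_seq
    trees, retained, clade_section = {}, {}, {}
    evidence_contigs = ds.proteome_ids | filtered_ids
    for fam in sorted(family_members):
        members = family_members[fam]
        if len(members) < 2:
            continue
        dm = phylo.distance_matrix(members)
        tree = phylo.midpoint_root(phylo.nj_tree(dm))
        evid = {cid for cid in members if cds_contig[cid] in evidence_contigs}
        kept = phylo.clade_evidence_filter(tree, evid, d_max)
        trees[fam], retained[fam] = tree, kept
        clade_section[fam] = {
            "n_leaves": len(members), "n_evidence": len(evid),
            "n_retained": len(kept), "retained": sorted(kept),
        }

    # 5. evaluation
    proteome = ds.proteome_ids
    truth_toxins = ds.toxin_ids
    venn = evaluation.venn_counts(predicted_contigs)
    fp_rates, pr_table, stage_counts = {}, {}, {}
    for tier in TIER_ORDER:
        res = annotations[tier]
        fp_rates[tier] = {
            "sp_positive": _fpr_or_none(predicted_contigs[tier], proteome),
            "filtered": _fpr_or_none(filtered_contigs[tier], proteome),
        }
        pr_table[tier] = {
            "unfiltered": _pr_or_none(predicted_contigs[tier], truth_toxins),
            "filtered": _pr_or_none(filtered_contigs[tier], truth_toxins),
        }
        stage_counts[tier] = res.stage_counts

    # combined dataset: the union of the three tiers' predictions
    union_pred = set().union(*predicted_contigs.values())
    pr_table["combined"] = {
        "unfiltered": _pr_or_none(union_pred, truth_toxins),
        "filtered": _pr_or_none(union_pred & filtered_ids, truth_toxins),
    }
    fp_rates["combined"] = {
        "sp_positive": _fpr_or_none(union_pred, proteome),
        "filtered": _fpr_or_none(union_pred & filtered_ids, proteome),
    }

    fam_of_contig = dict(zip(ds.truth["id"], ds.truth["family"]))
    tier_fams = {t: [a.family for a in annotations[t].assignments]
                 for t in TIER_ORDER if annotations[t].assignments}
    proteome_fams = [fam_of_contig[c] for c in sorted(proteome)]
    diversity = (evaluation.family_diversity_profile(tier_fams, proteome_fams)
                 if proteome_fams and tier_fams else pd.DataFrame(
                     columns=["tier", "family", "pct", "delta_pp", "fold"]))

    det_expr = expression.detection_expression_table(
        {"proteome": proteome, **predicted_contigs}, expr)

    retention = (len(filtered_ids & proteome) / len(proteome)) if proteome else 0.0

    mature_a = {}
    for assign, cds in zip(annotations["species"].assignments,
                           annotations["species"].survivors):
        mature_a[cds.id] = cds.mature_seq
    if mature_a and ds.popB_mature:
        intraspecific = evaluation.intraspecific_overlap(
            mature_a, ds.popB_mature, cluster_thresholds)
    else:
        intraspecific = {thr: None for thr in cluster_thresholds}

    report = evaluation.build_report(
        venn=venn, fp_rates=fp_rates, stage_counts=stage_counts,
        precision_recall_table=pr_table, diversity=diversity,
        intraspecific=intraspecific, detection_expression=det_expr,
        filter_retention=retention, clade_filter=clade_section)

    return RunResult(dataset=ds, cds_list=cds_list, annotations=annotations,
                     predicted_contigs=predicted_contigs, expression=expr,
                     proteome_ids=proteome, filtered_ids=filtered_ids,
                     filtered_contigs=filtered_contigs, trees=trees,
                     retained=retained, report=report)


def run_pipeline(run_config: RunConfig) -> dict:
    """Execute all stages and write every intermediate under ``out_dir``.

    Returns the evaluation report (also written as report.json).
    Deterministic given the seed: two runs produce byte-identical reports.
    """
    os.makedirs(run_config.out_dir, exist_ok=True)
    if run_config.inputs is not None:
        ds = load_real_inputs(run_config.inputs)
        sp_mode = "heuristic"
    else:
        sim = run_config.simulation
        if sim.seed != run_config.seed:
            sim = SimulationConfig(**{**sim.to_dict(), "seed": run_config.seed})
        ds = simulate.simulate_dataset(sim)
        simulate.write_dataset(ds, os.path.join(run_config.out_dir, "dataset"))
        sp_mode = run_config.sp_mode
    result = _analyse(ds, run_config.filter_params, run_config.scheme,
                      run_config.e_threshold, run_config.d_max,
                      run_config.cluster_thresholds, sp_mode)
    out = run_config.out_dir
    simulate.write_fasta({c.id: c.aa_seq for c in result.cds_list},
                         os.path.join(out, "orfs.faa"))
    for tier, res in result.annotations.items():
        homology.write_hits_tsv((a.best_hit for a in res.assignments),
                                os.path.join(out, f"hits_{tier}.tsv"))
    expression.write_expression_tsv(result.expression, os.path.join(out, "expression.tsv"))
    treedir = os.path.join(out, "trees")
    os.makedirs(treedir, exist_ok=True)
    cds_contig = {c.id: c.contig_id for c in result.cds_list}
    for fam, tree in result.trees.items():
        phylo.annotate_and_export(
            tree, result.expression, result.proteome_ids, result.retained[fam],
            os.path.join(treedir, f"{fam}.nwk"),
            os.path.join(treedir, f"{fam}_leaves.tsv"),
            id_map=cds_contig)
    evaluation.write_report(result.report, os.path.join(out, "report.json"))
    return result.report


def load_real_inputs(paths: Mapping[str, object]) -> SyntheticDataset:
    """Adapt on-disk inputs (contigs FASTA, counts TSV, proteome id list,
    per-tier database FASTAs) to the in-memory dataset interface. Ground
    truth is unavailable, so truth-dependent report sections stay empty and
    signal peptides use the heuristic predictor."""
    from Bio import SeqIO
    contigs = {r.id: str(r.seq) for r in SeqIO.parse(str(paths["contigs"]), "fasta")}
    counts = pd.read_csv(str(paths["counts"]), sep="\t")
    with open(str(paths["proteome"])) as fh:
        proteome = {line.strip() for line in fh if line.strip()}
    databases = {}
    for tier, p in dict(paths["databases"]).items():
        entries = []
        for r in SeqIO.parse(str(p), "fasta"):
            family, _, subject = r.id.partition("|")
            entries.append(homology.DatabaseEntry(family=family, subject_id=subject or r.id,
                                                  seq=str(r.seq)))
        databases[tier] = entries
    truth = pd.DataFrame({
        "id": sorted(contigs), "family": "", "population": "A",
        "is_toxin": False, "is_secreted": False, "complete": False,
        "length_bp": [len(contigs[c]) for c in sorted(contigs)],
        "sp_seq": "", "protein": "", "mature_protein": "",
    })
    return SyntheticDataset(config=SimulationConfig(), families=[], contigs=contigs,
                            truth=truth, counts=counts, proteome_ids=proteome,
                            databases=databases, popB_mature={})


# ---------------------------------------------------------------------------
# declarative configuration

_TOP_KEYS = {"seed", "simulation", "inputs", "filter", "e_threshold", "d_max",
             "cluster_thresholds", "sp_mode", "out_dir"}
_FILTER_KEYS = {"min_fpkm_vg", "min_fold", "pseudocount"}
_SIM_KEYS = set(SimulationConfig.__dataclass_fields__)
_INPUT_KEYS = {"contigs", "counts", "proteome", "databases"}


def _unknown(key: str, valid: set[str]) -> str:
    hint = difflib.get_close_matches(key, valid, n=1)
    return f"unknown key {key!r}" + (f" (did you mean {hint[0]!r}?)" if hint else "")


def validate_config(path) -> RunConfig:
    """Load and normalize a YAML run configuration.

    All defaults are resolved; unknown keys are rejected with a suggestion;
    every problem is reported at once in the raised error.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(_unknown(key, _TOP_KEYS))
    for section, valid in (("simulation", _SIM_KEYS), ("filter", _FILTER_KEYS),
                           ("inputs", _INPUT_KEYS)):
        for key in (raw.get(section) or {}):
            if key not in valid:
                errors.append(_unknown(f"{section}.{key}", {f"{section}.{v}" for v in valid}))
    seed = raw.get("seed", 0)
    filt = raw.get("filter") or {}
    sim_raw = raw.get("simulation")
    inputs = raw.get("inputs")
    if sim_raw is not None and inputs is not None:
        errors.append("provide either 'inputs' or 'simulation', not both")
    try:
        filter_params = FilterParams(**filt)
    except (TypeError, ValueError) as exc:
        errors.append(f"filter: {exc}")
        filter_params = FilterParams()
    simulation = None
    if inputs is None:
        sim_kwargs = dict(sim_raw or {})
        sim_kwargs.setdefault("seed", seed)
        if "leaves_per_family" in sim_kwargs:
            sim_kwargs["leaves_per_family"] = tuple(sim_kwargs["leaves_per_family"])
        for key in ("vg_logFPKM_toxin", "vg_logFPKM_nontoxin", "muscle_logFPKM"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        try:
            simulation = SimulationConfig(**{k: v for k, v in sim_kwargs.items()
                                             if k in _SIM_KEYS})
        except ValueError as exc:
            errors.append(f"simulation: {exc}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(
        seed=seed, simulation=simulation, inputs=inputs,
        filter_params=filter_params,
        e_threshold=float(raw.get("e_threshold", homology.DEFAULT_EVALUE)),
        d_max=raw.get("d_max", "median"),
        cluster_thresholds=tuple(raw.get("cluster_thresholds", (0.95, 0.90))),
        sp_mode=raw.get("sp_mode", "truth"),
        out_dir=raw.get("out_dir", "toxannot_out"),
    )
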