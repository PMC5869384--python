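"""Synthetic venom-gland/muscle transcriptome benchmarks with full ground truth.

The generator emulates the statistical structure the annotation audit relies
on, at desk scale:

* toxin gene families whose members diverge on birth-death (Yule) trees, with
  one recruited toxin clade per family evolving faster than its non-toxin
  paralogues (accelerated evolution after venom recruitment);
* venom-gland vs. muscle expression where toxins are strongly venom-gland
  upregulated, sampled on the FPKM scale and converted to integer fragment
  counts by multinomial allocation of each library;
* proteomic detection of secreted toxins with probability increasing
  logistically in venom-gland expression;
* contigs with UTRs and in-frame stops delimiting the CDS, a fraction of
  which are emitted 5'- or 3'-truncated (losing the signal peptide or part of
  the mature region);
* N-terminal signal peptides on secreted sequences (toxins and a fraction of
  non-toxin paralogues — secreted housekeeping homologues are exactly the
  false-positive class homology annotation struggles with);
* three reference-database tiers of increasing relatedness (distant
  "ToxProt-like" / lineage / species) plus decoy families; and
* a second diverged "population" of each toxin for intraspecific-overlap
  tests.

All randomness derives from a single seed; identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .expression import BACKGROUND_ID
from .scoring import DEFAULT_SCHEME

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# Robinson-Robinson style background amino-acid frequencies.
BACKGROUND_FREQS = np.array([
    0.078, 0.051, 0.045, 0.054, 0.019, 0.043, 0.063, 0.074, 0.022, 0.051,
    0.090, 0.057, 0.022, 0.039, 0.052, 0.071, 0.058, 0.013, 0.032, 0.064,
])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

# One representative codon per amino acid for back-translation; ORF extraction
# only requires stop-free frames, so codon usage realism is not modelled.
CODON_OF = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGC",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

HYDROPHOBIC = "LIVFAM"


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic benchmark.

    Log-FPKM parameters are (mean, sd) on the log10 scale. ``subst_rate`` is
    the expected substitutions/site from the family root to a (non-toxin)
    leaf; recruited toxin clades evolve ``toxin_rate_multiplier`` times
    faster. ``db_divergence`` is the extra divergence of the distant
    ("ToxProt-like") database representatives from the family root; lineage
    representatives sit at half that. ``frag_prob`` is a free parameter of
    the generator (assembly fragmentation rate), not an empirical estimate.
    """

    seed: int = 0
    n_families: int = 4
    leaves_per_family: tuple[int, int] = (12, 20)
    birth_rate: float = 1.0
    root_length_aa: int = 90
    subst_rate: float = 0.5
    toxin_clade_fraction: float = 0.8
    toxin_rate_multiplier: float = 3.0
    p_secreted_nontoxin: float = 0.5
    vg_logFPKM_toxin: tuple[float, float] = (2.5, 0.7)
    vg_logFPKM_nontoxin: tuple[float, float] = (0.8, 0.7)
    muscle_logFPKM: tuple[float, float] = (0.8, 0.7)
    detection_slope: float = 1.5
    detection_intercept: float = -3.0
    frag_prob: float = 0.25
    db_divergence: float = 0.8
    distant_coverage: float = 0.75
    n_decoy_families: int = 3
    population_divergence: float = 0.25
    library_size_vg: int = 1_000_000
    library_size_muscle: int = 1_000_000

    def __post_init__(self) -> None:
        errs = []
        if self.seed < 0 or self.seed >= 2**31:
            errs.append("seed must be in [0, 2^31)")
        if self.n_families < 1:
            errs.append("n_families must be >= 1")
        lo, hi = self.leaves_per_family
        if not (2 <= lo <= hi):
            errs.append("leaves_per_family must satisfy 2 <= lo <= hi")
        for name in ("birth_rate", "subst_rate", "toxin_rate_multiplier",
                     "db_divergence", "population_divergence"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0")
        for name in ("toxin_clade_fraction", "frag_prob", "p_secreted_nontoxin",
                     "distant_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                errs.append(f"{name} must be in [0, 1]")
        if self.root_length_aa < 1:
            errs.append("root_length_aa must be >= 1")
        if self.library_size_vg < 0 or self.library_size_muscle < 0:
            errs.append("library sizes must be >= 0")
        for name in ("vg_logFPKM_toxin", "vg_logFPKM_nontoxin", "muscle_logFPKM"):
            if getattr(self, name)[1] < 0:
                errs.append(f"{name} sd must be >= 0")
        if errs:
            raise ConfigurationError("; ".join(errs))

    def family_rng(self, family_index: int) -> np.random.Generator:
        """Per-family stream: reproducible under partial regeneration."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(family_index,)))

    def stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(10_000 + stage,)))

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# substitution process

def _conditional_matrix() -> np.ndarray:
    """P(b | a) for a replacement event: proportional to p_b * 2^(s_ab/2),
    b != a — i.e. BLOSUM62-consistent conservative replacement."""
    m = DEFAULT_SCHEME.matrix
    n = len(AMINO_ACIDS)
    cond = np.zeros((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                cond[i, j] = BACKGROUND_FREQS[j] * 2 ** (m[a, b] / 2)
        cond[i] /= cond[i].sum()
    return cond


CONDITIONAL = _conditional_matrix()
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def random_protein(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=BACKGROUND_FREQS)
    return "".join(AMINO_ACIDS[i] for i in idx)


def evolve(seq: str, t: float, rng: np.random.Generator) -> str:
    """Evolve a protein for expected ``t`` substitutions/site: per site a
    Poisson(t) number of replacement events, each drawn from the
    BLOSUM62-conditional distribution given the current residue."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if t == 0:
        return seq
    out = list(seq)
    n_events = rng.poisson(t, size=len(seq))
    for pos, k in enumerate(n_events):
        a = _AA_INDEX[out[pos]]
        for _ in range(k):
            a = rng.choice(len(AMINO_ACIDS), p=CONDITIONAL[a])
        out[pos] = AMINO_ACIDS[a]
    return "".join(out)


# ---------------------------------------------------------------------------
# trees

class SimNode:
    """Minimal tree node for the generator's birth-death trees."""

    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 children: list["SimNode"] | None = None):
        self.name = name
        self.length = length
        self.children = children or []

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["SimNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self) -> str:
        def fmt(node: "SimNode") -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6f}"
        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


def yule_tree(n_leaves: int, birth_rate: float, rng: np.random.Generator) -> SimNode:
    """Pure-birth topology with exponential branch lengths (rate
    ``birth_rate``), unscaled."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    scale = 1.0 / birth_rate if birth_rate > 0 else 1.0
    root = SimNode()
    root.children = [SimNode(name="t0"), SimNode(name="t1")]
    leaves = list(root.children)
    for k in range(2, n_leaves):
        split = leaves[rng.integers(len(leaves))]
        left, right = SimNode(name=split.name), SimNode(name=f"t{k}")
        split.children = [left, right]
        split.name = None
        leaves.remove(split)
        leaves.extend([left, right])
    for node in root.walk():
        if node is not root:
            node.length = float(rng.exponential(scale))
    return root


def _scale_depth(root: SimNode, target_depth: float) -> None:
    depths = []

    def rec(node: SimNode, acc: float) -> None:
        acc += node.length
        if node.is_leaf():
            depths.append(acc)
        for c in node.children:
            rec(c, acc)

    for c in root.children:
        rec(c, 0.0)
    mean = float(np.mean(depths))
    if mean <= 0:
        return
    f = target_depth / mean
    for node in root.walk():
        node.length *= f


# ---------------------------------------------------------------------------
# family simulation

@dataclass
class Family:
    index: int
    label: str
    tree: SimNode
    root_seq: str
    mature: dict[str, str]          # leaf id -> mature protein (population A)
    toxin_leaves: set[str]
    secreted: dict[str, str | None]  # leaf id -> signal peptide or None
    clade_anchor_seq: str            # sequence at the toxin clade ancestor (or root)
    truth: pd.DataFrame              # per-leaf ground truth (pre-emission)


def _make_signal_peptide(rng: np.random.Generator) -> str:
    core = "".join(HYDROPHOBIC[i] for i in rng.integers(0, len(HYDROPHOBIC), size=13))
    basic = "KR"[rng.integers(2)]
    return "M" + basic + core + "ASA"


def simulate_family(config: SimulationConfig, family_index: int) -> Family:
    """One gene family: a Yule tree scaled to ``subst_rate`` root-to-leaf
    depth, sequences evolved from a random root, one clade recruited as
    toxin with probability ``toxin_clade_fraction`` (faster-evolving,
    signal-peptide bearing), and secreted non-toxin paralogues elsewhere."""
    if family_index >= config.n_families:
        raise ConfigurationError("family_index out of range")
    rng = config.family_rng(family_index)
    label = f"FAM{family_index:02d}"
    n_leaves = int(rng.integers(config.leaves_per_family[0],
                                config.leaves_per_family[1] + 1))
    tree = yule_tree(n_leaves, config.birth_rate, rng)
    _scale_depth(tree, config.subst_rate)

    # choose the recruited toxin clade (3..60% of leaves when possible)
    toxin_leaves: set[str] = set()
    clade_node = None
    if rng.random() < config.toxin_clade_fraction:
        internal = [n for n in tree.walk()
                    if n is not tree and not n.is_leaf()]
        max_size = max(2, math.ceil(0.6 * n_leaves))
        candidates = [n for n in internal if 3 <= len(n.leaves()) <= max_size]
        if not candidates:
            candidates = [n for n in internal if len(n.leaves()) <= max_size] or internal
        clade_node = candidates[rng.integers(len(candidates))]
        for node in clade_node.walk():
            node.length *= config.toxin_rate_multiplier
        toxin_leaves = {l.name for l in clade_node.leaves()}

    root_seq = random_protein(config.root_length_aa, rng)
    mature: dict[str, str] = {}
    clade_anchor = {"seq": root_seq}

    def rec(node: SimNode, seq: str) -> None:
        seq = evolve(seq, node.length, rng)
        if node is clade_node:
            clade_anchor["seq"] = seq
        if node.is_leaf():
            mature[node.name] = seq
        for c in node.children:
            rec(c, seq)

    for c in tree.children:
        rec(c, root_seq)

    # rename leaves to stable family-scoped ids (preorder)
    renames = {}
    for i, leaf in enumerate(tree.leaves()):
        new = f"F{family_index:02d}L{i:02d}"
        renames[leaf.name] = new
        leaf.name = new
    mature = {renames[k]: v for k, v in mature.items()}
    toxin_leaves = {renames[k] for k in toxin_leaves}

    sp_toxin = _make_signal_peptide(rng)
    sp_house = _make_signal_peptide(rng)
    secreted: dict[str, str | None] = {}
    rows = []
    for leaf in sorted(mature):
        is_toxin = leaf in toxin_leaves
        if is_toxin:
            sp = sp_toxin
        elif rng.random() < config.p_secreted_nontoxin:
            sp = sp_house
        else:
            sp = None
        secreted[leaf] = sp
        rows.append((leaf, label, "A", is_toxin, sp is not None))
    truth = pd.DataFrame(rows, columns=["id", "family", "population",
                                        "is_toxin", "is_secreted"])
    return Family(index=family_index, label=label, tree=tree, root_seq=root_seq,
                  mature=mature, toxin_leaves=toxin_leaves, secreted=secreted,
                  clade_anchor_seq=clade_anchor["seq"], truth=truth)


# ---------------------------------------------------------------------------
# emission: back-translation, UTRs, fragmentation

def back_translate(protein: str) -> str:
    return "".join(CODON_OF[a] for a in protein)


def random_nt(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def fragment_and_emit(
    families: Iterable[Family],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Emit one nucleotide contig per population-A leaf, with in-frame stops
    delimiting the CDS and flanking UTRs; with probability ``frag_prob`` the
    contig is truncated 5' or 3' (side uniform), possibly removing the
    signal peptide or part of the mature region. Returns (contigs, truth)
    where truth records per-contig completeness, the emitted protein and the
    emitted signal peptide.
    """
    rng = rng if rng is not None else config.stage_rng(1)
    contigs: dict[str, str] = {}
    rows = []
    for fam in families:
        for leaf in sorted(fam.mature):
            sp = fam.secreted[leaf]
            protein = (sp or "") + fam.mature[leaf]
            complete = True
            emitted_sp = sp
            if rng.random() < config.frag_prob:
                complete = False
                side = "5" if rng.random() < 0.5 else "3"
                frac = rng.uniform(0.1, 0.6)
                n_cut = max(1, int(frac * len(protein)))
                if side == "5":
                    protein = protein[n_cut:]
                    emitted_sp = None  # start of CDS lost with the 5' end
                else:
                    protein = protein[:-n_cut]
                cds_nt = back_translate(protein)
                if side == "5":
                    contig = cds_nt + "TGA" + random_nt(int(rng.integers(20, 51)), rng)
                else:
                    contig = random_nt(int(rng.integers(20, 51)), rng) + "TAA" + cds_nt
            else:
                cds_nt = back_translate(protein)
                contig = (random_nt(int(rng.integers(20, 51)), rng) + "TAA"
                          + cds_nt + "TGA" + random_nt(int(rng.integers(20, 51)), rng))
            contigs[leaf] = contig
            rows.append((leaf, fam.label, "A", leaf in fam.toxin_leaves,
                         fam.secreted[leaf] is not None, complete, len(contig),
                         emitted_sp or "", protein,
                         protein[len(emitted_sp):] if emitted_sp else protein))
    truth = pd.DataFrame(rows, columns=[
        "id", "family", "population", "is_toxin", "is_secreted", "complete",
        "length_bp", "sp_seq", "protein", "mature_protein"])
    return contigs, truth


# ---------------------------------------------------------------------------
# expression / proteome

def simulate_expression(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fragment counts per tissue by multinomial allocation of each library.

    Per-contig target FPKMs are drawn log-normally per class (toxin vs.
    non-toxin in venom gland; a common muscle model); the implied library
    fractions leave the remainder of each library to an explicit background
    row (the unannotated transcriptome), so counts sum exactly to the
    library size.
    """
    rng = rng if rng is not None else config.stage_rng(2)
    ids = truth["id"].tolist()
    lengths = truth["length_bp"].to_numpy(dtype=float)
    is_toxin = truth["is_toxin"].to_numpy(dtype=bool)

    mu_t, sd_t = config.vg_logFPKM_toxin
    mu_n, sd_n = config.vg_logFPKM_nontoxin
    mu_m, sd_m = config.muscle_logFPKM
    log_vg = np.where(is_toxin, rng.normal(mu_t, sd_t, len(ids)),
                      rng.normal(mu_n, sd_n, len(ids)))
    log_mu = rng.normal(mu_m, sd_m, len(ids))
    fpkm_vg, fpkm_mu = 10.0 ** log_vg, 10.0 ** log_mu

    def allocate(fpkms: np.ndarray, library: int) -> np.ndarray:
        frac = fpkms * lengths / 1e9  # FPKM definition inverted
        total = frac.sum()
        if total >= 1.0:
            frac = frac / total
            bg = 0.0
        else:
            bg = 1.0 - total
        counts = rng.multinomial(library, np.append(frac, bg))
        return counts

    cv = allocate(fpkm_vg, config.library_size_vg)
    cm = allocate(fpkm_mu, config.library_size_muscle)
    df = pd.DataFrame({
        "id": ids + [BACKGROUND_ID],
        "length_bp": np.append(lengths, 1000).astype(int),
        "count_vg": cv,
        "count_muscle": cm,
    })
    return df


def simulate_proteome(
    truth: pd.DataFrame,
    expression: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> set[str]:
    """Detected-in-venom ids: each secreted toxin independently with
    probability logistic(intercept + slope * log10(FPKM_vg + 1));
    non-toxins are never detected."""
    rng = rng if rng is not None else config.stage_rng(3)
    fpkm_vg = dict(zip(expression["id"], expression["fpkm_vg"]))
    detected = set()
    eligible = truth[truth["is_toxin"] & truth["is_secreted"]]
    for cid in eligible["id"]:
        z = config.detection_intercept + config.detection_slope * math.log10(fpkm_vg[cid] + 1)
        p = 1.0 / (1.0 + math.exp(-z))
        if rng.random() < p:
            detected.add(cid)
    return detected


# ---------------------------------------------------------------------------
# database tiers and populations

def build_database_tiers(
    families: list[Family],
    truth: pd.DataFrame,
    proteome_ids: set[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, list]:
    """Three protein databases of decreasing relatedness to the transcriptome.

    species: the proteomically detected population-A sequences themselves;
    lineage: per family, two related-species representatives evolved by
    db_divergence/2 — a true toxin descended from the recruited clade's
    ancestor, and a "putative toxin" descended from the family root
    (compiled lineage toxin lists are over-inclusive and carry entries that
    are really non-toxin homologues); distant: deep-diverged representatives
    (family root evolved by db_divergence, reflecting independent venom
    recruitment in a distant lineage) for a ``distant_coverage`` subset of
    families, plus decoy families with no transcriptome homologue.
    """
    from .homology import DatabaseEntry  # local import to avoid cycle
    rng = rng if rng is not None else config.stage_rng(4)
    protein_of = dict(zip(truth["id"], truth["protein"]))
    species = [DatabaseEntry(family=fam, subject_id=f"{cid}_pr", seq=protein_of[cid])
               for cid, fam in sorted(zip(truth["id"], truth["family"]))
               if cid in proteome_ids and protein_of[cid]]
    lineage, distant = [], []
    for fam in families:
        lineage.append(DatabaseEntry(
            family=fam.label, subject_id=f"{fam.label}_lin",
            seq=evolve(fam.clade_anchor_seq, config.db_divergence / 2, rng)))
        lineage.append(DatabaseEntry(
            family=fam.label, subject_id=f"{fam.label}_put",
            seq=evolve(fam.root_seq, config.db_divergence / 2, rng)))
        if rng.random() < config.distant_coverage:
            distant.append(DatabaseEntry(
                family=fam.label, subject_id=f"{fam.label}_dst",
                seq=evolve(fam.root_seq, config.db_divergence, rng)))
    for k in range(config.n_decoy_families):
        distant.append(DatabaseEntry(
            family=f"DECOY{k:02d}", subject_id=f"DECOY{k:02d}_dst",
            seq=random_protein(config.root_length_aa, rng)))
    return {"species": species, "lineage": lineage, "distant": distant}


def population_b_mature(
    families: list[Family],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Mature toxin peptides of a second, diverged population (B)."""
    rng = rng if rng is not None else config.stage_rng(5)
    out = {}
    for fam in families:
        for leaf in sorted(fam.toxin_leaves):
            out[f"{leaf}B"] = evolve(fam.mature[leaf], config.population_divergence, rng)
    return out


# ---------------------------------------------------------------------------
# dataset bundle

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    families: list[Family]
    contigs: dict[str, str]
    truth: pd.DataFrame
    counts: pd.DataFrame
    proteome_ids: set[str]
    databases: dict[str, list]
    popB_mature: dict[str, str]

    @property
    def sp_truth_labels(self) -> dict[str, str | None]:
        """Contig id -> emitted signal peptide string (None if unsignalled)."""
        return {cid: (sp if sp else None)
                for cid, sp in zip(self.truth["id"], self.truth["sp_seq"])}

    @property
    def toxin_ids(self) -> set[str]:
        return set(self.truth.loc[self.truth["is_toxin"], "id"])


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the whole generator under one seed and bundle the results."""
    from .expression import expression_table
    families = [simulate_family(config, i) for i in range(config.n_families)]
    contigs, truth = fragment_and_emit(families, config)
    counts = simulate_expression(truth, config)
    expr = expression_table(counts)
    proteome_ids = simulate_proteome(truth, expr, config)
    truth = truth.assign(detected=truth["id"].isin(proteome_ids))
    databases = build_database_tiers(families, truth, proteome_ids, config)
    popb = population_b_mature(families, config)
    return SyntheticDataset(config=config, families=families, contigs=contigs,
                            truth=truth, counts=counts, proteome_ids=proteome_ids,
                            databases=databases, popB_mature=popb)


# ---------------------------------------------------------------------------
# writers

def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid in seqs:
            fh.write(f">{sid}\n{seqs[sid]}\n")


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write contigs/databases FASTA, truth and counts TSV, and the proteome
    id list under ``outdir``; deterministic byte-for-byte given the config."""
    import os
    os.makedirs(outdir, exist_ok=True)
    write_fasta(ds.contigs, os.path.join(outdir, "contigs.fasta"))
    for tier, entries in ds.databases.items():
        with open(os.path.join(outdir, f"db_{tier}.fasta"), "w") as fh:
            for e in entries:
                fh.write(f">{e.header}\n{e.seq}\n")
    write_fasta(ds.popB_mature, os.path.join(outdir, "population_b_mature.fasta"))
    cols = ["id", "family", "is_toxin", "is_secreted", "detected", "complete",
            "population"]
    ds.truth[cols].to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    ds.counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "proteome_ids.txt"), "w") as fh:
        for cid in sorted(ds.proteome_ids):
            fh.write(cid + "\n")
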