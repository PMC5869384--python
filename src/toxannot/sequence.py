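"""Sequence post-processing: ORF extraction, signal peptides, deduplication, clustering.

These are the steps a venom-gland transcriptome passes through after assembly
and before homology annotation: six-frame translation into candidate coding
sequences (CDSs), gating on a predicted N-terminal secretion signal, removal of
identical translations, and greedy identity clustering of mature peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .scoring import global_aligner

MIN_ORF_AA = 40

# Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: residues accepted at the -3/-1 positions of a signal-peptidase cleavage site
SMALL_RESIDUES = frozenset("AGSCT")


class SignalLabelMissingError(KeyError):
    """Raised when truth-mode signal peptide detection finds no label for a contig."""


@dataclass(frozen=True)
class CodingSequence:
    """A translated open reading frame: the unit of toxin annotation.

    Coordinates are 0-based half-open on the *forward* strand of the contig,
    for both forward and reverse frames. ``is_complete`` means the ORF is
    bounded by in-frame stop codons on both sides within the contig; an ORF
    running into a contig end is treated as open (a partial CDS).
    """

    id: str
    contig_id: str
    frame: int  # {-3..-1, +1..+3}
    start: int
    end: int
    aa_seq: str
    is_complete: bool
    signal_peptide: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if "*" in self.aa_seq:
            raise ValueError("aa_seq must not contain stop symbols")
        if self.end - self.start != 3 * len(self.aa_seq):
            raise ValueError("span length must equal 3 x protein length")

    @property
    def mature_seq(self) -> str:
        """Protein sequence with the signal peptide (if annotated) removed."""
        if self.signal_peptide is None:
            return self.aa_seq
        return self.aa_seq[self.signal_peptide[1]:]


@dataclass
class Cluster:
    """A greedy identity cluster; the representative is the longest member."""

    representative_id: str
    member_ids: list[str]
    threshold: float


def extract_orfs(contig_id: str, contig: str, min_len_aa: int = MIN_ORF_AA) -> list[CodingSequence]:
    """Translate a contig in all six frames and return every maximal stop-free
    stretch of at least ``min_len_aa`` residues.

    No start codon is required: candidate CDSs are stop-to-stop (or
    stop-to-contig-end, in which case they are flagged incomplete). Codons
    containing N translate to X. Reverse-strand ORFs are reported in
    forward-strand coordinates with a negative frame.
    """
    contig = contig.upper()
    if not contig:
        return []
    bad = set(contig) - set("ACGTN")
    if bad:
        raise ValueError(f"contig contains non-nucleotide symbols: {sorted(bad)}")
    length = len(contig)
    out: list[CodingSequence] = []
    for strand in (+1, -1):
        seq = contig if strand == 1 else str(Seq(contig).reverse_complement())
        for offset in range(3):
            n_codons = (length - offset) // 3
            if n_codons <= 0:
                continue
            sub = seq[offset:offset + 3 * n_codons]
            aa = str(Seq(sub).translate())
            frame = strand * (offset + 1)
            # split into stop-free segments, tracking codon positions
            pos = 0
            for seg_index, seg in enumerate(aa.split("*")):
                if len(seg) >= min_len_aa:
                    codon_start = pos
                    # bounded on the left iff preceded by a stop codon
                    left_closed = seg_index > 0
                    # bounded on the right iff followed by a stop codon
                    right_closed = codon_start + len(seg) < len(aa)
                    # nt span in the translated strand
                    s_nt = offset + 3 * codon_start
                    e_nt = s_nt + 3 * len(seg)
                    if strand == 1:
                        start, end = s_nt, e_nt
                    else:
                        start, end = length - e_nt, length - s_nt
                    out.append(CodingSequence(
                        id=f"{contig_id}|f{frame:+d}|{start}-{end}",
                        contig_id=contig_id,
                        frame=frame,
                        start=start,
                        end=end,
                        aa_seq=seg,
                        is_complete=left_closed and right_closed,
                    ))
                pos += len(seg) + 1  # +1 for the stop
    out.sort(key=lambda c: (c.start, c.end, c.frame))
    return out


def signal_peptide_heuristic(
    aa_seq: str,
    search_len: int = 30,
    min_window: int = 8,
    min_hydropathy: float = 1.6,
) -> int | None:
    """Rule-based signal peptide call; returns the cleavage position or None.

    This is a deliberately simple, documented stand-in for a neural-network
    predictor. Within the first ``search_len`` residues it requires (i) at
    least one K/R in positions 1-5 (the n-region charge), (ii) a run of
    ``min_window`` consecutive residues with mean Kyte-Doolittle hydropathy
    >= ``min_hydropathy`` (the h-region), and (iii) small residues (A/G/S/C/T)
    at the -3 and -1 positions of the proposed cleavage site (the c-region
    Ala-X-Ala rule). The earliest admissible cleavage position wins.
    """
    region = aa_seq[:search_len]
    if len(region) < min_window + 3:
        return None
    if not any(r in "KR" for r in region[:5]):
        return None
    kd = [KYTE_DOOLITTLE.get(r, -4.5) for r in region]
    prefix = [0.0]
    for v in kd:
        prefix.append(prefix[-1] + v)
    window_end = None  # earliest end of a qualifying hydrophobic window
    for i in range(len(region) - min_window + 1):
        j = i + min_window
        if (prefix[j] - prefix[i]) / min_window >= min_hydropathy:
            window_end = j
            break
    if window_end is None:
        return None
    for c in range(max(window_end, 4), len(region) + 1):
        if region[c - 1] in SMALL_RESIDUES and region[c - 3] in SMALL_RESIDUES:
            return c
    return None


def detect_signal_peptide(
    cds: CodingSequence,
    mode: str = "truth",
    truth_labels: Mapping[str, str | None] | None = None,
) -> tuple[bool, int | None]:
    """Decide whether a CDS carries an N-terminal signal peptide.

    ``truth`` mode reads generator-provided labels: ``truth_labels`` maps
    contig id to the signal peptide residue string (or None for unsignalled
    contigs); a CDS is positive iff its translation starts with that string
    (a 5'-truncated CDS that lost the signal peptide is negative).
    ``heuristic`` mode applies :func:`signal_peptide_heuristic`.
    """
    if not cds.aa_seq:
        raise ValueError("empty protein sequence")
    if mode == "heuristic":
        cleave = signal_peptide_heuristic(cds.aa_seq)
        return (cleave is not None), cleave
    if mode == "truth":
        if truth_labels is None or cds.contig_id not in truth_labels:
            raise SignalLabelMissingError(
                f"no ground-truth signal peptide label for contig {cds.contig_id!r}")
        sp = truth_labels[cds.contig_id]
        if sp and cds.aa_seq.startswith(sp):
            return True, len(sp)
        return False, None
    raise ValueError(f"unknown mode {mode!r}")


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity, with the shorter sequence as denominator.

    Identical aligned positions are counted under a BLOSUM62 global alignment
    with the same affine gap costs as the homology search; dividing by the
    shorter sequence's length follows the CD-HIT convention, so a fragment
    that matches a full-length sequence end-to-end scores 1.0.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    # canonical argument order: co-optimal alignments can differ in identity
    # count, so symmetry is enforced by construction
    if b < a:
        a, b = b, a
    aligner = global_aligner()
    aln = aligner.align(a, b)[0]
    ident = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        for qa, sb in zip(a[qs:qe], b[ss:se]):
            if qa == sb:
                ident += 1
    return ident / min(len(a), len(b))


def dedupe_identical(cds_list: Sequence[CodingSequence]) -> list[CodingSequence]:
    """Collapse exact-duplicate translations.

    Among duplicates the CDS with the lexicographically smallest id survives;
    survivors keep the input order of each sequence's first occurrence.
    """
    best: dict[str, CodingSequence] = {}
    order: list[str] = []
    for cds in cds_list:
        if cds.aa_seq not in best:
            best[cds.aa_seq] = cds
            order.append(cds.aa_seq)
        elif cds.id < best[cds.aa_seq].id:
            best[cds.aa_seq] = cds
    return [best[seq] for seq in order]


def cluster_by_identity(
    seqs: Mapping[str, str],
    threshold: float,
) -> list[Cluster]:
    """Greedy incremental identity clustering (CD-HIT style).

    Sequences are visited longest-first (ties by id); each joins the first
    existing cluster whose representative it matches at >= ``threshold``
    identity, else founds a new cluster. Deterministic for a given input set.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    clusters: list[Cluster] = []
    for sid in ordered:
        seq = seqs[sid]
        for cl in clusters:
            if pairwise_identity(seq, seqs[cl.representative_id]) >= threshold:
                cl.member_ids.append(sid)
                break
        else:
            clusters.append(Cluster(representative_id=sid, member_ids=[sid], threshold=threshold))
    return clusters


def write_cluster_table(clusters: Iterable[Cluster], seqs: Mapping[str, str], path) -> None:
    """Write a cluster table TSV: cluster_id, representative, member, identity."""
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative\tmember\tidentity\n")
        for i, cl in enumerate(clusters):
            rep = seqs[cl.representative_id]
            for m in cl.member_ids:
                ident = 1.0 if m == cl.representative_id else pairwise_identity(seqs[m], rep)
                fh.write(f"{i}\t{cl.representative_id}\t{m}\t{ident:.4f}\n")
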