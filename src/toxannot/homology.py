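"""Local-alignment homology search and best-hit family assignment.

Replaces a seeded blastp search with exact Smith-Waterman under the same
scoring (BLOSUM62, gap open 11 / extend 1) and Karlin-Altschul E-value
statistics, so the candidate toxin lists can only be a superset of what a
heuristic word-seeded search would return. Queries are annotated with the
family of their best (highest bit score) database hit, then gated on signal
peptide presence and deduplicated — the standard homology-tier annotation
pipeline for venom-gland transcriptomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .scoring import DEFAULT_SCHEME, ScoringScheme, local_aligner, sanitize_protein
from .sequence import CodingSequence, dedupe_identical, detect_signal_peptide

DEFAULT_EVALUE = 1e-3


@dataclass(frozen=True)
class DatabaseEntry:
    """A reference database sequence carrying its toxin family label."""

    family: str
    subject_id: str
    seq: str

    @property
    def header(self) -> str:
        return f"{self.family}|{self.subject_id}"


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    family: str
    raw_score: float
    bitscore: float
    evalue: float
    identity: float
    query_span: tuple[int, int]  # 0-based half-open
    subject_span: tuple[int, int]


@dataclass(frozen=True)
class FamilyAssignment:
    query_id: str
    family: str
    best_hit: HomologyHit


@dataclass
class AnnotationResult:
    """Survivor assignments plus the four-stage count summary
    (unique contigs / unique CDS / unique CDS with signal peptide /
    unique full-length CDS)."""

    assignments: list[FamilyAssignment]
    survivors: list[CodingSequence]
    stage_counts: dict[str, int]


def sw_align(
    query: str,
    subject: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Optimal local alignment score and spans under the scheme.

    Returns ``(raw_score, query_span, subject_span)`` with 0-based half-open
    spans covering the aligned region. The empty alignment scores 0.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    q, s = sanitize_protein(query), sanitize_protein(subject)
    aligner = local_aligner(scheme)
    score = aligner.score(q, s)
    if score <= 0:
        return 0.0, (0, 0), (0, 0)
    aln = aligner.align(q, s)[0]
    qblocks, sblocks = aln.aligned
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    sspan = (int(sblocks[0][0]), int(sblocks[-1][1]))
    return float(score), qspan, sspan


def sw_score(query: str, subject: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Score-only fast path for :func:`sw_align`."""
    if not query or not subject:
        raise ValueError("empty sequence")
    score = local_aligner(scheme).score(sanitize_protein(query), sanitize_protein(subject))
    return float(max(score, 0.0))


def evalue(
    raw_score: float,
    query_len: int,
    db_residues: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("sequence/database lengths must be positive")
    return scheme.k * query_len * db_residues * math.exp(-scheme.lam * raw_score)


def _alignment_identity(q: str, s: str, aln) -> float:
    ident = aligned_cols = 0
    prev_qe = prev_se = None
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        if prev_qe is not None:
            aligned_cols += (qs - prev_qe) + (ss - prev_se)  # gap columns
        prev_qe, prev_se = qe, se
        aligned_cols += qe - qs
        for qa, sb in zip(q[qs:qe], s[ss:se]):
            if qa == sb:
                ident += 1
    return ident / aligned_cols if aligned_cols else 0.0


def search(
    queries: Mapping[str, str],
    database: Sequence[DatabaseEntry],
    e_threshold: float = DEFAULT_EVALUE,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[HomologyHit]:
    """All query-subject pairs with E <= ``e_threshold``.

    ``n`` in the E-value is the total residue count of the database tier
    being searched. No query-coverage filter is applied.
    """
    if not database:
        raise ValueError("empty database")
    n_total = sum(len(e.seq) for e in database)
    aligner = local_aligner(scheme)
    hits: list[HomologyHit] = []
    for qid in sorted(queries):
        q = sanitize_protein(queries[qid])
        if not q:
            continue
        for entry in database:
            s = sanitize_protein(entry.seq)
            score = float(aligner.score(q, s))
            if score <= 0:
                continue
            e = evalue(score, len(q), n_total, scheme)
            if e <= e_threshold:
                aln = aligner.align(q, s)[0]
                qblocks, sblocks = aln.aligned
                hits.append(HomologyHit(
                    query_id=qid,
                    subject_id=entry.subject_id,
                    family=entry.family,
                    raw_score=score,
                    bitscore=scheme.bitscore(score),
                    evalue=e,
                    identity=_alignment_identity(q, s, aln),
                    query_span=(int(qblocks[0][0]), int(qblocks[-1][1])),
                    subject_span=(int(sblocks[0][0]), int(sblocks[-1][1])),
                ))
    return hits


def assign_families(hits: Iterable[HomologyHit]) -> list[FamilyAssignment]:
    """Per query, the family of the maximal-bitscore hit.

    Ties are broken by lowest E-value, then lexicographic subject id.
    Queries without hits are simply absent from the result.
    """
    best: dict[str, HomologyHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or (-hit.bitscore, hit.evalue, hit.subject_id) < (
                -cur.bitscore, cur.evalue, cur.subject_id):
            best[hit.query_id] = hit
    return [FamilyAssignment(qid, best[qid].family, best[qid])
            for qid in sorted(best)]


def annotate_dataset(
    cds_list: Sequence[CodingSequence],
    database: Sequence[DatabaseEntry],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    e_threshold: float = DEFAULT_EVALUE,
    sp_mode: str = "truth",
    sp_truth_labels: Mapping[str, str | None] | None = None,
    exclude_ids: frozenset[str] | set[str] | None = None,
) -> AnnotationResult:
    """Run the full annotation pipeline for one database tier.

    Stage order: homology search -> best-hit family assignment -> keep
    signal-peptide-positive CDSs -> remove identical sequences. Stage counts
    report unique contigs, unique CDSs, unique CDSs with signal peptide and
    unique full-length (stop-bounded) CDSs among the annotated candidates.
    ``exclude_ids`` models the manual-inspection removal step as an explicit
    id blacklist.
    """
    exclude = exclude_ids or set()
    cds_by_id = {c.id: c for c in cds_list if c.id not in exclude}
    counts = {"unique_contigs": 0, "unique_cds": 0,
              "unique_cds_signal_peptide": 0, "unique_full_length_cds": 0}
    if not cds_by_id:
        return AnnotationResult([], [], counts)
    hits = search({i: c.aa_seq for i, c in cds_by_id.items()},
                  database, e_threshold, scheme)
    assignments = assign_families(hits)
    annotated = [cds_by_id[a.query_id] for a in assignments]
    assignment_by_id = {a.query_id: a for a in assignments}

    sp_flags: dict[str, tuple[bool, int | None]] = {}
    for cds in annotated:
        sp_flags[cds.id] = detect_signal_peptide(cds, sp_mode, sp_truth_labels)

    with_sp = [c for c in annotated if sp_flags[c.id][0]]
    survivors = dedupe_identical(with_sp)
    # carry the detected cleavage onto survivors so mature peptides are derivable
    survivors = [
        CodingSequence(
            id=c.id, contig_id=c.contig_id, frame=c.frame, start=c.start,
            end=c.end, aa_seq=c.aa_seq, is_complete=c.is_complete,
            signal_peptide=(0, sp_flags[c.id][1]),
        )
        for c in survivors
    ]
    counts["unique_contigs"] = len({c.contig_id for c in annotated})
    counts["unique_cds"] = len({c.aa_seq for c in annotated})
    counts["unique_cds_signal_peptide"] = len({c.aa_seq for c in with_sp})
    counts["unique_full_length_cds"] = len({c.aa_seq for c in with_sp if c.is_complete})
    return AnnotationResult(
        assignments=[assignment_by_id[c.id] for c in survivors],
        survivors=survivors,
        stage_counts=counts,
    )


def write_hits_tsv(hits: Iterable[HomologyHit], path) -> None:
    """Write hits in a blastp outfmt-6-like column order (0-based half-open spans)."""
    with open(path, "w") as fh:
        fh.write("# qid\tsid\tpident\tlength\tqstart\tqend\tsstart\tsend\tevalue\tbitscore"
                 " (spans 0-based half-open)\n")
        for h in hits:
            alen = h.query_span[1] - h.query_span[0]
            fh.write(f"{h.query_id}\t{h.subject_id}\t{100 * h.identity:.2f}\t{alen}\t"
                     f"{h.query_span[0]}\t{h.query_span[1]}\t{h.subject_span[0]}\t"
                     f"{h.subject_span[1]}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n")
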