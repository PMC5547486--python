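"""Candidate-sequence curation filters.

The upstream homology search (PSI-BLAST against NCBI with an E-value cutoff
of 1e-60) is outside this package; its output -- a set of candidate protein
sequences -- is the input here.  Two reproducible filters are applied:

1. a strict length filter (default: keep sequences strictly longer than 240
   residues; a relaxed 200-residue threshold is used for the fast-evolving
   SIAH3-style search), and
2. a domain-region filter: the candidate, globally aligned to a reference
   ortholog, must cover at least a configurable fraction (default 0.5) of
   the reference's functional-domain-containing region with non-gap
   characters.  The published selection applied this criterion by eye; the
   coverage fraction is this package's quantitative proxy for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .conservation import DomainMap
from .core_io import GAP, SequenceRecord
from .substitution import AA_INDEX


@dataclass
class CurationConfig:
    min_length_default: int = 240
    min_length_relaxed: int = 200
    require_domain_region_alignment: bool = True
    min_region_coverage: float = 0.5
    reference_ids: dict[str, str] = field(default_factory=dict)
    #: provenance only; the remote search is not re-run here
    evalue_cutoff: float = 1e-60

    def __post_init__(self) -> None:
        if self.min_length_relaxed > self.min_length_default:
            raise ValueError("relaxed length threshold must not exceed the default")
        if self.evalue_cutoff <= 0:
            raise ValueError("E-value cutoff must be positive")


@dataclass
class CurationReport:
    kept: list[str]
    discarded: list[tuple[str, str]]
    counts_per_group: dict[str, int]

    def __post_init__(self) -> None:
        kept, disc = set(self.kept), {i for i, _ in self.discarded}
        if kept & disc:
            raise ValueError(f"ids both kept and discarded: {sorted(kept & disc)}")

    @property
    def all_ids(self) -> set[str]:
        return set(self.kept) | {i for i, _ in self.discarded}

    def to_frame(self, records: list[SequenceRecord] | None = None) -> pd.DataFrame:
        reasons = dict(self.discarded)
        meta = {r.id: r for r in records} if records else {}
        rows = []
        for rid in sorted(self.all_ids):
            rec = meta.get(rid)
            rows.append({
                "id": rid,
                "length": rec.ungapped_length() if rec else pd.NA,
                "group": rec.group_label if rec else "unknown",
                "decision": "keep" if rid in set(self.kept) else "discard",
                "reason": reasons.get(rid, ""),
            })
        return pd.DataFrame(rows)


def _make_report(kept_recs, discarded) -> CurationReport:
    counts: dict[str, int] = {}
    for r in kept_recs:
        counts[r.group_label] = counts.get(r.group_label, 0) + 1
    return CurationReport(kept=[r.id for r in kept_recs], discarded=discarded,
                          counts_per_group=counts)


def load_reference_label_table() -> pd.DataFrame:
    """The family's curated dataset labels (accession, species, paralog
    group for the 70 reference sequences), shipped as a package asset."""
    with resources.as_file(resources.files("sinaphy.data")
                           / "table1_labels.tsv") as path:
        return pd.read_csv(path, sep="\t", comment="#",
                           names=["accession", "species", "group"])


def filter_by_length(candidates: list[SequenceRecord], threshold: int,
                     strict: bool = True) -> CurationReport:
    """Keep records longer than ``threshold`` residues (strictly, by
    default, matching the published '>240' / '>200' criteria)."""
    kept, discarded = [], []
    for rec in candidates:
        n = rec.ungapped_length()
        ok = n > threshold if strict else n >= threshold
        if ok:
            kept.append(rec)
        else:
            discarded.append((rec.id, f"length {n} not > {threshold}"))
    return _make_report(kept, discarded)


_ALIGNER = None


def _global_aligner() -> Align.PairwiseAligner:
    """Global protein aligner with fixed published scoring (BLOSUM62,
    gap open -11 / extend -1) so the coverage filter is reproducible."""
    global _ALIGNER
    if _ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _ALIGNER = aligner
    return _ALIGNER


def domain_region_coverage(candidate: SequenceRecord, reference: SequenceRecord,
                           ref_domains: DomainMap,
                           pairwise: tuple[str, str] | None = None) -> float:
    """Fraction of the reference's domain-containing region (first domain
    start to last domain end) covered by non-gap candidate characters in a
    global pairwise alignment.  A pre-computed alignment (two equal-length
    gapped strings, reference first) may be supplied."""
    lo, hi = ref_domains.region
    if hi > reference.ungapped_length():
        raise ValueError(f"domain region {lo}-{hi} exceeds reference length "
                         f"{reference.ungapped_length()}")
    if pairwise is None:
        # X is outside BLOSUM62's alphabet in some biopython builds; map to A
        # for scoring only (coverage counts any non-gap character anyway)
        def scoreable(s: str) -> str:
            return "".join(ch if ch in AA_INDEX else "A" for ch in s)
        aln = _global_aligner().align(scoreable(reference.ungapped),
                                      scoreable(candidate.ungapped))[0]
        ref_row, cand_row = str(aln[0]), str(aln[1])
    else:
        ref_row, cand_row = pairwise
        if len(ref_row) != len(cand_row):
            raise ValueError("pairwise alignment rows differ in length")
    covered = total = 0
    ref_pos = 0
    for r_ch, c_ch in zip(ref_row, cand_row):
        if r_ch != GAP:
            ref_pos += 1
            if lo <= ref_pos <= hi:
                total += 1
                if c_ch != GAP:
                    covered += 1
    if total == 0:
        raise ValueError("empty domain region")
    return covered / total


def filter_by_domain_region(candidates: list[SequenceRecord],
                            reference: SequenceRecord, ref_domains: DomainMap,
                            min_region_coverage: float = 0.5,
                            pairwise_alignments: dict[str, tuple[str, str]] | None = None
                            ) -> CurationReport:
    """Keep candidates whose global alignment to the reference covers at
    least ``min_region_coverage`` of the reference's domain region."""
    kept, discarded = [], []
    for rec in candidates:
        pre = pairwise_alignments.get(rec.id) if pairwise_alignments else None
        cov = domain_region_coverage(rec, reference, ref_domains, pairwise=pre)
        if cov >= min_region_coverage:
            kept.append(rec)
        else:
            discarded.append((rec.id, f"domain-region coverage {cov:.2f} "
                                      f"< {min_region_coverage:.2f}"))
    return _make_report(kept, discarded)


def curate(candidates: list[SequenceRecord], config: CurationConfig,
           reference: SequenceRecord | None = None,
           ref_domains: DomainMap | None = None,
           relaxed: bool = False) -> CurationReport:
    """Length filter, then (optionally) the domain-region filter."""
    threshold = config.min_length_relaxed if relaxed else config.min_length_default
    report = filter_by_length(candidates, threshold)
    if config.require_domain_region_alignment and reference is not None \
            and ref_domains is not None:
        survivors = [r for r in candidates if r.id in set(report.kept)]
        second = filter_by_domain_region(survivors, reference, ref_domains,
                                         config.min_region_coverage)
        report = CurationReport(kept=second.kept,
                                discarded=report.discarded + second.discarded,
                                counts_per_group=second.counts_per_group)
    return report
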