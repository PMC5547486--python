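"""Domain maps, conservation profiling, and consensus sequences.

A :class:`DomainMap` names the family's functional domains (RING, SZF, SBS,
DIMER, and the SIAH3-unique N-terminal S3UNS) as 1-based inclusive residue
spans on an *ungapped* reference sequence.  Mapping those spans through the
reference row of an alignment yields alignment-column spans, from which we
compute:

* per-sequence percent identity against the reference ("not excluding gaps":
  gap and X columns stay in the denominator and never match);
* per-column conservation classes (identical / similar / divergent), where
  "similar" means all non-gap residues fall in one strong-similarity group;
* pass/fail checks for invariant residues such as the zinc-coordinating
  Cys/His positions of the RING and SZF domains;
* majority-rule consensus sequences with 'X' marking frequency ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AMBIGUOUS, AMINO_ACIDS, GAP, Alignment, SequenceRecord

DOMAIN_NAMES = ("RING", "SZF", "SBS", "DIMER", "S3UNS")

#: strong-similarity amino-acid grouping used for the "similar" class
DEFAULT_SIMILARITY_GROUPS = (
    frozenset("ILVM"), frozenset("FWY"), frozenset("KRH"), frozenset("DE"),
    frozenset("NQ"), frozenset("ST"), frozenset("AG"), frozenset("C"),
    frozenset("P"),
)


@dataclass
class DomainMap:
    """Named domain spans in 1-based ungapped reference coordinates."""

    reference_id: str
    spans: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        seen: list[tuple[int, int]] = []
        for name, (start, end) in self.spans.items():
            if name not in DOMAIN_NAMES:
                raise ValueError(f"unknown domain name {name!r}")
            if not (1 <= start <= end):
                raise ValueError(f"domain {name}: bad span {start}-{end}")
            for s, e in seen:
                if start <= e and s <= end:
                    raise ValueError(f"domain {name}: span overlaps another domain")
            seen.append((start, end))

    @property
    def region(self) -> tuple[int, int]:
        """Start of the first domain to the end of the last domain."""
        starts = [s for s, _ in self.spans.values()]
        ends = [e for _, e in self.spans.values()]
        return min(starts), max(ends)

    def ordered(self) -> list[tuple[str, int, int]]:
        return sorted(((n, s, e) for n, (s, e) in self.spans.items()),
                      key=lambda x: x[1])


def read_domain_maps(path) -> dict[str, DomainMap]:
    """Read the tab-separated annotation format
    ``name<TAB>reference_id<TAB>domain<TAB>start<TAB>end``."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["name", "reference_id", "domain", "start", "end"])
    out: dict[str, DomainMap] = {}
    for name, grp in df.groupby("name", sort=False):
        ref_ids = grp["reference_id"].unique()
        if len(ref_ids) != 1:
            raise ValueError(f"domain map {name!r}: inconsistent reference ids")
        spans = {row.domain: (int(row.start), int(row.end))
                 for row in grp.itertuples()}
        out[str(name)] = DomainMap(reference_id=str(ref_ids[0]), spans=spans)
    return out


def write_domain_maps(maps: dict[str, DomainMap], path) -> None:
    with open(path, "w") as fh:
        fh.write("# name\treference_id\tdomain\tstart\tend\n")
        for name, dmap in maps.items():
            for dom, s, e in dmap.ordered():
                fh.write(f"{name}\t{dmap.reference_id}\t{dom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# coordinate mapping

def residue_to_column(aln: Alignment, reference_id: str) -> np.ndarray:
    """1-based alignment column of each ungapped reference residue."""
    ref = aln.record(reference_id)
    cols = np.array([j for j, ch in enumerate(ref.residues, start=1) if ch != GAP],
                    dtype=np.int64)
    return cols


def map_domains_to_columns(aln: Alignment, dmap: DomainMap) -> dict[str, tuple[int, int]]:
    """Domain spans translated to 1-based alignment-column spans."""
    cols = residue_to_column(aln, dmap.reference_id)
    n_res = len(cols)
    out = {}
    for name, (start, end) in dmap.spans.items():
        if end > n_res:
            raise ValueError(f"domain {name}: span {start}-{end} exceeds ungapped "
                             f"reference length {n_res}")
        out[name] = (int(cols[start - 1]), int(cols[end - 1]))
    return out


# ---------------------------------------------------------------------------
# identity and conservation classes

def percent_identity(aln: Alignment, reference_id: str,
                     span: tuple[int, int] | None = None,
                     skip_columns_missing_in: str | None = None) -> pd.Series:
    """Percent identity of every record against the reference over a 1-based
    inclusive column span (default: whole alignment).

    Gaps are *not excluded*: a column where either sequence is '-' or 'X'
    counts in the denominator and cannot match.  ``skip_columns_missing_in``
    drops columns where the named (incomplete) record is '-' from the
    denominator of every comparison -- used when a truncated database entry
    would otherwise masquerade as divergence.
    """
    if span is None:
        span = (1, aln.n_columns)
    lo, hi = span
    if not (1 <= lo <= hi <= aln.n_columns):
        raise ValueError(f"span {span} outside alignment 1..{aln.n_columns}")
    ref = np.array(list(aln.record(reference_id).residues[lo - 1:hi]))
    keep = np.ones(ref.shape, dtype=bool)
    if skip_columns_missing_in is not None:
        inc = np.array(list(aln.record(skip_columns_missing_in).residues[lo - 1:hi]))
        keep = inc != GAP
    if not keep.any():
        raise ValueError("no columns left after dropping incomplete-sequence gaps")
    out = {}
    matchable = np.array([ch not in (GAP, AMBIGUOUS) for ch in ref])
    for rec in aln.records:
        seq = np.array(list(rec.residues[lo - 1:hi]))
        seq_ok = np.array([ch not in (GAP, AMBIGUOUS) for ch in seq])
        matches = (seq == ref) & matchable & seq_ok & keep
        out[rec.id] = 100.0 * matches.sum() / keep.sum()
    return pd.Series(out, name="percent_identity")


def column_classes(aln: Alignment, span: tuple[int, int] | None = None,
                   similarity_groups=DEFAULT_SIMILARITY_GROUPS) -> pd.DataFrame:
    """Classify each column in a span as identical / similar / divergent.

    ``identical``: every record carries the same amino acid (no gaps/X).
    ``similar``: not identical, but all non-gap, non-X residues fall within a
    single similarity group.  Everything else is ``divergent``.
    """
    if span is None:
        span = (1, aln.n_columns)
    lo, hi = span
    rows = []
    for j in range(lo, hi + 1):
        col = aln.column(j)
        residues = {ch for ch in col if ch not in (GAP, AMBIGUOUS)}
        has_missing = any(ch in (GAP, AMBIGUOUS) for ch in col)
        if len(residues) == 1 and not has_missing:
            cls = "identical"
        elif residues and any(residues <= grp for grp in similarity_groups):
            cls = "similar"
        else:
            cls = "divergent"
        rows.append({"column": j, "class": cls})
    return pd.DataFrame(rows)


def unanimous_count(aln: Alignment, span: tuple[int, int]) -> tuple[int, int]:
    """(number of identical columns, total columns) over a span."""
    classes = column_classes(aln, span)
    return int((classes["class"] == "identical").sum()), len(classes)


def check_invariant_residues(aln: Alignment, reference_id: str,
                             positions, allowed) -> pd.Series:
    """Per-record pass/fail: does the record hold a residue from ``allowed``
    at every listed reference residue coordinate?"""
    cols = residue_to_column(aln, reference_id)
    allowed = set(allowed)
    col_idx = []
    for p in positions:
        if not 1 <= p <= len(cols):
            raise ValueError(f"residue position {p} not mappable "
                             f"(reference has {len(cols)} residues)")
        col_idx.append(int(cols[p - 1]) - 1)
    out = {}
    for rec in aln.records:
        out[rec.id] = all(rec.residues[j] in allowed for j in col_idx)
    return pd.Series(out, name="invariant_ok")


# ---------------------------------------------------------------------------
# consensus

@dataclass
class ConsensusSequence:
    """Majority-rule consensus; 'X' exactly where two or more residues tie
    for the highest frequency.  Gap-only columns are dropped; ``columns``
    keeps the 1-based source-alignment column of every consensus position so
    consensus sequences from a shared alignment stay comparable."""

    residues: str
    columns: np.ndarray
    source_id: str = ""
    winning_frequency: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.residues)


def build_consensus(aln: Alignment, source_id: str = "") -> ConsensusSequence:
    """Per column: count amino-acid frequencies ignoring gaps; emit the
    unique maximal residue, or 'X' on a tie; drop gap-only columns."""
    residues, columns, winfreq = [], [], []
    for j in range(1, aln.n_columns + 1):
        col = aln.column(j)
        counts: dict[str, int] = {}
        for ch in col:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            continue
        best = max(counts.values())
        winners = [aa for aa, c in counts.items() if c == best]
        residues.append(winners[0] if len(winners) == 1 else AMBIGUOUS)
        columns.append(j)
        winfreq.append(best / sum(counts.values()))
    if not residues:
        raise ValueError("alignment has no non-gap columns")
    return ConsensusSequence("".join(residues), np.array(columns, dtype=np.int64),
                             source_id=source_id,
                             winning_frequency=np.array(winfreq))


def consensus_joint_alignment(consensuses: list[ConsensusSequence],
                              ids: list[str] | None = None) -> Alignment:
    """Joint alignment of consensus sequences that came from a *shared*
    coordinate system (e.g. per-group consensuses of one family alignment):
    positions are merged on their source columns; absences become gaps."""
    if ids is None:
        ids = [c.source_id or f"consensus_{i}" for i, c in enumerate(consensuses)]
    all_cols = sorted(set().union(*(set(c.columns.tolist()) for c in consensuses)))
    col_pos = {c: i for i, c in enumerate(all_cols)}
    records = []
    for cid, cons in zip(ids, consensuses):
        row = [GAP] * len(all_cols)
        for ch, col in zip(cons.residues, cons.columns):
            row[col_pos[int(col)]] = ch
        records.append(SequenceRecord(id=cid, residues="".join(row)))
    return Alignment(records, column_map=np.array(all_cols, dtype=np.int64))


def _consensus_identity(joint: Alignment, reference_id: str,
                        span: tuple[int, int]) -> pd.Series:
    """Identity against a reference consensus, in the reference's own
    coordinate system: columns where the reference row is gapped (positions
    private to other consensuses in the joint alignment) leave the
    denominator, and characters match by strict equality -- so a consensus
    is 100% identical to itself, while an 'X' against a resolved residue
    (or a gap) is a mismatch."""
    lo, hi = span
    ref = np.array(list(joint.record(reference_id).residues[lo - 1:hi]))
    keep = ref != GAP
    if not keep.any():
        raise ValueError("reference consensus is empty over this span")
    out = {}
    for rec in joint.records:
        seq = np.array(list(rec.residues[lo - 1:hi]))
        out[rec.id] = 100.0 * ((seq == ref) & keep).sum() / keep.sum()
    return pd.Series(out, name="consensus_identity")


def compare_consensus(joint: Alignment, reference_id: str,
                      domain_spans: dict[str, tuple[int, int]] | None = None
                      ) -> pd.DataFrame:
    """Percent identity of each consensus row against a reference consensus,
    per domain span (alignment-column coordinates) and over the whole
    reference length (see :func:`_consensus_identity` for the matching
    rule)."""
    columns = {}
    if domain_spans:
        for name, span in domain_spans.items():
            columns[name] = _consensus_identity(joint, reference_id, span)
    columns["WHOLE"] = _consensus_identity(joint, reference_id,
                                           (1, joint.n_columns))
    return pd.DataFrame(columns)
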