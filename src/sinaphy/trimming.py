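"""Alignment column trimming.

Three procedures, each preserving record order and composing the alignment's
``column_map`` so trimmed coordinates remain traceable:

* :func:`trim_low_coverage` -- remove columns where the gap fraction is
  strictly greater than a threshold (default 0.70, i.e. keep columns with at
  least 30% sequence coverage; a column with exactly 70% gaps stays).
* :func:`trim_to_reference` -- remove columns that are gaps in a designated
  reference row, optionally restricted to a column region and protecting
  reference-residue spans (by default the functional domains, so in-domain
  reference gaps survive the trim).
* :func:`trim_private_overhang` -- drop a maximal terminal run of columns in
  which at most one record has non-gap characters (a single-species overhang).
"""

from __future__ import annotations

import numpy as np

from .conservation import DomainMap, map_domains_to_columns
from .core_io import GAP, Alignment


def gap_fractions(aln: Alignment) -> np.ndarray:
    mat = aln.to_matrix()
    return (mat == GAP).sum(axis=0) / aln.n_records


def trim_low_coverage(aln: Alignment, max_gap_fraction: float = 0.70) -> Alignment:
    """Remove every column whose gap fraction exceeds ``max_gap_fraction``
    (strict inequality)."""
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    keep = np.nonzero(gap_fractions(aln) <= max_gap_fraction)[0]
    if keep.size == aln.n_columns:
        return aln
    return aln.take_columns(keep)


def trim_to_reference(aln: Alignment, reference_id: str,
                      region: tuple[int, int] | str = "all",
                      protect_spans: list[tuple[int, int]] | None = None,
                      domain_map: DomainMap | None = None) -> Alignment:
    """Remove columns where the reference row has a gap.

    ``region`` restricts the trim to a 1-based inclusive column range
    (columns outside it are never removed).  ``protect_spans`` are reference
    *residue* ranges whose alignment columns are never removed; when a
    ``domain_map`` is given and no explicit spans are passed, the functional
    domains are protected.
    """
    ref = aln.record(reference_id)  # raises KeyError for unknown ids
    if region == "all":
        lo, hi = 1, aln.n_columns
    else:
        lo, hi = region
        if not (1 <= lo <= hi <= aln.n_columns):
            raise ValueError(f"region {region} outside alignment")
    protected = np.zeros(aln.n_columns, dtype=bool)
    if protect_spans is None and domain_map is not None:
        col_spans = map_domains_to_columns(aln, domain_map).values()
        for cs, ce in col_spans:
            protected[cs - 1:ce] = True
    elif protect_spans:
        if domain_map is not None:
            raise ValueError("pass either protect_spans or domain_map, not both")
        # residue spans -> column spans through the reference row
        from .conservation import residue_to_column
        cols = residue_to_column(aln, reference_id)
        for rs, re_ in protect_spans:
            if not 1 <= rs <= re_ <= len(cols):
                raise ValueError(f"protect span {rs}-{re_} exceeds reference")
            protected[cols[rs - 1] - 1:cols[re_ - 1]] = True
    drop = np.zeros(aln.n_columns, dtype=bool)
    for j in range(lo - 1, hi):
        if ref.residues[j] == GAP and not protected[j]:
            drop[j] = True
    keep = np.nonzero(~drop)[0]
    if keep.size == aln.n_columns:
        return aln
    return aln.take_columns(keep)


def trim_private_overhang(aln: Alignment, end: str) -> Alignment:
    """Remove the maximal terminal run of columns in which at most one
    record is non-gap, from the N ('N') or C ('C') terminus."""
    if end not in ("N", "C"):
        raise ValueError("end must be 'N' or 'C'")
    mat = aln.to_matrix()
    nongap_per_col = (mat != GAP).sum(axis=0)
    n = aln.n_columns
    run = 0
    rng = range(n) if end == "N" else range(n - 1, -1, -1)
    for j in rng:
        if nongap_per_col[j] <= 1:
            run += 1
        else:
            break
    if run == 0 or run == n:
        return aln if run == 0 else aln  # full-overhang alignment left intact
    keep = np.arange(run, n) if end == "N" else np.arange(0, n - run)
    return aln.take_columns(keep)
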