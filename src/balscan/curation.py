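"""Reading and curating per-gene coding alignments.

The pipeline starts from a gapped multiple alignment of the coding region of
one gene: an ingroup of *S. cerevisiae* strains (one of which is the S288C
reference) plus, optionally, one aligned outgroup sequence (*S. paradoxus*
CBS432).  Before any population-genetic statistic is computed the alignment
is cleaned deterministically:

1. ingroup strains whose ungapped sequence is shorter than a configured
   fraction of the ungapped reference length are dropped;
2. ingroup strains carrying an internal stop codon in the reference frame
   are dropped;
3. a base inserted in exactly one retained record (a column that is a gap in
   every other record, reference and outgroup included) is treated as a
   sequencing error: the base is removed and the column deleted;
4. two-allele IUPAC ambiguity codes (heterozygous base calls) are resolved
   by choosing one of the two encoded nucleotides uniformly at random with a
   seeded generator; codes encoding more than two nucleotides become ``N``.

The four rules are applied in that fixed order, and every modification is
appended to a curation log, so curation is reproducible and replayable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

from .exceptions import AlignmentFormatError, ConfigurationError, CurationError

# IUPAC two-nucleotide ambiguity codes (heterozygous calls).
AMBIGUITY_2 = {
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
}
# Codes encoding three or four nucleotides are demoted to N.
AMBIGUITY_MANY = set("BDHV")

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class CurationAction:
    strain_id: str
    action: str
    column: Optional[int]  # 0-based alignment column, None if not columnar
    detail: str

    def as_row(self) -> tuple:
        col = "" if self.column is None else str(self.column + 1)
        return (self.strain_id, self.action, col, self.detail)


@dataclass
class RawAlignment:
    """An uncurated gapped alignment as read from FASTA."""

    gene_id: str
    records: list[tuple[str, str]]  # (strain_id, aligned sequence), order kept
    reference_id: str
    outgroup_id: Optional[str] = None

    def __post_init__(self):
        if not self.records:
            raise AlignmentFormatError(f"{self.gene_id}: no records")
        length = len(self.records[0][1])
        for sid, seq in self.records:
            if len(seq) != length:
                raise AlignmentFormatError(
                    f"{self.gene_id}: record {sid!r} has length {len(seq)}, "
                    f"expected {length}"
                )
        ids = [sid for sid, _ in self.records]
        if self.reference_id not in ids:
            raise KeyError(
                f"{self.gene_id}: reference {self.reference_id!r} not in alignment"
            )
        if self.outgroup_id is not None and self.outgroup_id not in ids:
            raise KeyError(
                f"{self.gene_id}: outgroup {self.outgroup_id!r} not in alignment"
            )

    @property
    def length(self) -> int:
        return len(self.records[0][1])


@dataclass
class GeneAlignment:
    """A curated in-frame ingroup alignment, plus optional aligned outgroup.

    ``records`` holds the retained ingroup strains (reference included) in
    input order; the outgroup sequence, when present, is stored separately so
    ingroup statistics never accidentally include it.  Codon coordinates are
    defined by the reference frame: alignment columns where the reference has
    a base, taken three at a time.
    """

    gene_id: str
    records: list[tuple[str, str]]
    reference_id: str
    outgroup: Optional[tuple[str, str]] = None
    frame_offset: int = 0  # codons skipped at the 5' end of the reference
    curation_log: list[CurationAction] = field(default_factory=list)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_strains(self) -> int:
        return len(self.records)

    @property
    def strain_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def sequence(self, strain_id: str) -> str:
        for sid, seq in self.records:
            if sid == strain_id:
                return seq
        if self.outgroup is not None and self.outgroup[0] == strain_id:
            return self.outgroup[1]
        raise KeyError(strain_id)

    @property
    def reference_seq(self) -> str:
        return self.sequence(self.reference_id)

    def reference_columns(self) -> np.ndarray:
        """Alignment columns where the reference has a base (the CDS frame)."""
        ref = np.frombuffer(self.reference_seq.encode(), dtype="S1")
        return np.flatnonzero(ref != b"-")

    def codon_matrix(self, include_outgroup: bool = True):
        """Project the alignment onto the reference frame.

        Returns ``(ids, M)`` where ``M`` is a character array of shape
        (n_sequences, L_ref) restricted to reference-base columns, L_ref a
        multiple of 3 (trailing columns beyond the last complete codon are
        dropped), with the outgroup (if requested and present) as last row.
        """
        cols = self.reference_columns()
        ncod = (len(cols) - 3 * self.frame_offset) // 3
        cols = cols[3 * self.frame_offset : 3 * self.frame_offset + 3 * ncod]
        rows = list(self.records)
        if include_outgroup and self.outgroup is not None:
            rows = rows + [self.outgroup]
        ids = [sid for sid, _ in rows]
        mat = np.array([list(seq) for _, seq in rows], dtype="U1")[:, cols]
        return ids, mat

    def as_raw(self) -> RawAlignment:
        records = list(self.records)
        outgroup_id = None
        if self.outgroup is not None:
            records.append(self.outgroup)
            outgroup_id = self.outgroup[0]
        return RawAlignment(
            gene_id=self.gene_id,
            records=records,
            reference_id=self.reference_id,
            outgroup_id=outgroup_id,
        )


def read_gene_alignment(
    path, reference_id: str, outgroup_id: Optional[str] = None, gene_id: Optional[str] = None
) -> RawAlignment:
    """Read one gene's FASTA alignment, preserving record order.

    Sequence case is normalised to upper; lengths must agree.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if len(records) < 2:
        raise AlignmentFormatError(f"{path}: need at least 2 records")
    length = len(records[0][1])
    for sid, seq in records:
        if len(seq) != length:
            raise AlignmentFormatError(
                f"{path}: record {sid!r} has length {len(seq)}, expected {length}"
            )
    if gene_id is None:
        import os

        gene_id = os.path.splitext(os.path.basename(str(path)))[0]
    return RawAlignment(gene_id, records, reference_id, outgroup_id)


def write_gene_alignment(aln: GeneAlignment, path) -> None:
    """Write the curated alignment (outgroup last) back to FASTA."""
    with open(path, "w") as fh:
        rows = list(aln.records)
        if aln.outgroup is not None:
            rows.append(aln.outgroup)
        for sid, seq in rows:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_curation_log(aln: GeneAlignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("strain_id\taction\tcolumn\tdetail\n")
        for act in aln.curation_log:
            fh.write("\t".join(act.as_row()) + "\n")


def _ungapped_len(seq: str) -> int:
    return len(seq) - seq.count("-")


def _internal_stop_codon(seq_in_frame: str) -> Optional[int]:
    """Return the 0-based codon index of the first internal stop, or None.

    The terminal codon is not internal; gapped/ambiguous codons are skipped
    (they cannot be confidently called as stops).
    """
    ncod = len(seq_in_frame) // 3
    for j in range(ncod - 1):
        codon = seq_in_frame[3 * j : 3 * j + 3]
        if codon in STOP_CODONS:
            return j
    return None


def curate_strains(
    raw: RawAlignment,
    min_length_fraction: float,
    seed: Optional[int] = None,
) -> GeneAlignment:
    """Apply the four cleanup rules (length, stop, insertion, ambiguity).

    ``min_length_fraction`` is the minimum ungapped length of a retained
    ingroup strain relative to the ungapped reference (0.99 for control
    genes, 0.90 for candidate genes).  ``seed`` drives the resolution of
    heterozygous base calls and is mandatory when any are present; the
    generator is consumed in record order then column order, so the result
    does not depend on file-system ordering.
    """
    if not (0 < min_length_fraction <= 1):
        raise ConfigurationError("min_length_fraction must be in (0, 1]")

    log: list[CurationAction] = []
    out_id = raw.outgroup_id
    ref_seq = dict(raw.records)[raw.reference_id]
    ref_len = _ungapped_len(ref_seq)
    ref_cols = [i for i, c in enumerate(ref_seq) if c != "-"]
    ncod = len(ref_cols) // 3

    ingroup = [(sid, seq) for sid, seq in raw.records if sid != out_id]
    outgroup = None
    if out_id is not None:
        outgroup = (out_id, dict(raw.records)[out_id])

    # 1. length rule -------------------------------------------------------
    kept = []
    for sid, seq in ingroup:
        ulen = _ungapped_len(seq)
        if ulen < min_length_fraction * ref_len:
            log.append(
                CurationAction(
                    sid,
                    "drop_short",
                    None,
                    f"ungapped length {ulen} < {min_length_fraction:g} x {ref_len}",
                )
            )
        else:
            kept.append((sid, seq))
    ingroup = kept

    # 2. internal stop codons in the reference frame -----------------------
    kept = []
    for sid, seq in ingroup:
        frame = "".join(seq[i] for i in ref_cols[: 3 * ncod])
        stop_at = _internal_stop_codon(frame)
        if stop_at is not None and sid != raw.reference_id:
            log.append(
                CurationAction(
                    sid, "drop_stop", None, f"internal stop at codon {stop_at + 1}"
                )
            )
        else:
            kept.append((sid, seq))
    ingroup = kept

    # 3. unique single-base insertions -------------------------------------
    # Columns gapped in the reference where exactly one retained record
    # (outgroup included) carries a base.
    all_rows = ingroup + ([outgroup] if outgroup is not None else [])
    length = raw.length
    drop_cols = set()
    for col in range(length):
        if ref_seq[col] != "-":
            continue
        carriers = [sid for sid, seq in all_rows if seq[col] != "-"]
        if len(carriers) == 1:
            drop_cols.add(col)
            log.append(
                CurationAction(
                    carriers[0],
                    "remove_unique_insertion",
                    col,
                    "single-base insertion absent from all other records",
                )
            )
    if drop_cols:
        keep_cols = [i for i in range(length) if i not in drop_cols]

        def strip(seq: str) -> str:
            return "".join(seq[i] for i in keep_cols)

        ingroup = [(sid, strip(seq)) for sid, seq in ingroup]
        if outgroup is not None:
            outgroup = (outgroup[0], strip(outgroup[1]))

    # 4. ambiguity codes ---------------------------------------------------
    all_rows = ingroup + ([outgroup] if outgroup is not None else [])
    has_ambiguity = any(
        c in AMBIGUITY_2 or c in AMBIGUITY_MANY for _, seq in all_rows for c in set(seq)
    )
    rng = None
    if has_ambiguity:
        if seed is None:
            raise ConfigurationError(
                f"{raw.gene_id}: ambiguity codes present but no seed given"
            )
        rng = np.random.default_rng(seed)

    def resolve(sid: str, seq: str) -> str:
        chars = list(seq)
        for col, c in enumerate(chars):
            if c in AMBIGUITY_2:
                choice = AMBIGUITY_2[c][int(rng.integers(2))]
                chars[col] = choice
                log.append(
                    CurationAction(
                        sid, "resolve_heterozygote", col, f"{c} -> {choice}"
                    )
                )
            elif c in AMBIGUITY_MANY:
                chars[col] = "N"
                log.append(
                    CurationAction(sid, "mask_ambiguity", col, f"{c} -> N")
                )
        return "".join(chars)

    if has_ambiguity:
        ingroup = [(sid, resolve(sid, seq)) for sid, seq in ingroup]
        if outgroup is not None:
            outgroup = (outgroup[0], resolve(outgroup[0], outgroup[1]))

    if len(ingroup) < 2:
        raise CurationError(
            f"{raw.gene_id}: fewer than 2 ingroup strains survive curation"
        )

    return GeneAlignment(
        gene_id=raw.gene_id,
        records=ingroup,
        reference_id=raw.reference_id,
        outgroup=outgroup,
        frame_offset=0,
        curation_log=log,
    )
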