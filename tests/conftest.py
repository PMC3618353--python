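"""Shared fixtures and alignment-building helpers."""

from __future__ import annotations

import pytest

from balscan.curation import GeneAlignment, RawAlignment


def make_aln(seqs, outgroup=None, gene_id="toy", reference_id=None, ids=None):
    """Build a GeneAlignment from plain ingroup sequences (first = reference)."""
    if ids is None:
        ids = [f"s{i:02d}" for i in range(len(seqs))]
    if reference_id is None:
        reference_id = ids[0]
    return GeneAlignment(
        gene_id=gene_id,
        records=list(zip(ids, seqs)),
        reference_id=reference_id,
        outgroup=None if outgroup is None else ("outgroup", outgroup),
    )


def make_raw(seqs_by_id, reference_id, outgroup_id=None, gene_id="toy"):
    return RawAlignment(
        gene_id=gene_id,
        records=list(seqs_by_id.items()),
        reference_id=reference_id,
        outgroup_id=outgroup_id,
    )


@pytest.fixture
def fasta_writer(tmp_path):
    def write(seqs_by_id, name="gene.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for sid, seq in seqs_by_id.items():
                fh.write(f">{sid}\n{seq}\n")
        return path

    return write
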