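import pytest

from pairedab.io_formats import (
    ChainAnnotation,
    PairedDataset,
    PairedRecord,
    parse_gene_label,
)


def make_chain(
    locus="IGH",
    v="IGHV1-2*01",
    j="IGHJ4*01",
    c="IGHM",
    coverage=50.0,
    seq_nt="ACGT",
    seq_aa="MA",
    positions=None,
):
    return ChainAnnotation(
        locus=locus,
        v_call=parse_gene_label(v),
        j_call=parse_gene_label(j),
        c_call=parse_gene_label(c),
        productive=True,
        coverage=coverage,
        sequence_nt=seq_nt,
        sequence_aa=seq_aa,
        imgt_positions=dict(positions or {}),
    )


def make_record(
    study="s1",
    cell="c1",
    h_seq="ACGTAC",
    l_seq="TTGGCC",
    h_aa="MAH",
    l_aa="MAL",
    h_v="IGHV1-2*01",
    l_v="IGKV1-5*01",
    l_locus="IGK",
    l_j="IGKJ1*01",
    l_c="IGKC",
    h_positions=None,
    l_positions=None,
):
    return PairedRecord(
        study_id=study,
        cell_id=cell,
        heavy=make_chain(seq_nt=h_seq, seq_aa=h_aa, v=h_v, positions=h_positions),
        light=make_chain(
            locus=l_locus, v=l_v, j=l_j, c=l_c,
            seq_nt=l_seq, seq_aa=l_aa, positions=l_positions,
        ),
    )


def make_dataset(records):
    ds = PairedDataset(records=list(records))
    ds.validate()
    return ds


@pytest.fixture
def small_null_repertoire():
    """A 5k-cell null repertoire (no enrichment) with default profiles."""
    from pairedab.synthetic_data import RepertoireConfig, simulate_paired_repertoire

    return simulate_paired_repertoire(RepertoireConfig(n_cells=5000, seed=42))
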