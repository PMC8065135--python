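import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myomethix import formats_io as fio
from myomethix.errors import FormatError, ValidationError
from tests.conftest import make_matrices, make_sample_sheet


# ---------------------------------------------------------------------------
# matrices / sheets / manifests
# ---------------------------------------------------------------------------

def write_toy_cohort(tmp_path, beta_override=None):
    sheet = make_sample_sheet(n_per_group=1)           # 2 subjects x 2 states
    expr = make_matrices(sheet, 3, seed=1, kind="expression")
    beta = make_matrices(sheet, 4, seed=2, kind="beta")
    manifest = fio.ProbeManifest(pd.DataFrame({
        "probe_id": list(beta.feature_ids),
        "chromosome": ["1", "2", "3", "4"],
        "nearest_gene": ["F000", "F001", "", "F002"],
        "gene_region": ["TSS200", "Body", "intergenic", "5'UTR"],
        "island_region": ["Island", "OpenSea", "OpenSea", "N_Shore"],
    }))
    fio.write_matrix_tsv(expr, tmp_path / "expression.tsv", "gene_id",
                         {"seed": 1})
    if beta_override is not None:
        beta_override(beta, tmp_path / "beta.tsv")
    else:
        fio.write_matrix_tsv(beta, tmp_path / "beta.tsv", "probe_id")
    fio.write_manifest_tsv(manifest, tmp_path / "manifest.tsv")
    fio.write_sample_sheet_tsv(sheet, tmp_path / "samples.tsv")
    return sheet, expr, beta, manifest


def test_cohort_round_trip_identity(tmp_path):
    sheet, expr, beta, manifest = write_toy_cohort(tmp_path)
    bundle = fio.read_cohort(tmp_path / "expression.tsv", tmp_path / "beta.tsv",
                             tmp_path / "manifest.tsv", tmp_path / "samples.tsv")
    assert bundle.expression == expr
    assert bundle.beta == beta
    assert bundle.samples == sheet
    assert bundle.manifest == manifest


def test_beta_out_of_range_names_probe_and_sample(tmp_path):
    def corrupt(beta, path):
        values = beta.values.copy()
        values[1, 2] = 1.2
        frame = pd.DataFrame(values, index=list(beta.feature_ids),
                             columns=list(beta.sample_ids))
        frame.index.name = "probe_id"
        frame.to_csv(path, sep="\t")

    sheet, *_ = write_toy_cohort(tmp_path, beta_override=corrupt)
    with pytest.raises(FormatError) as err:
        fio.read_cohort(tmp_path / "expression.tsv", tmp_path / "beta.tsv",
                        tmp_path / "manifest.tsv", tmp_path / "samples.tsv")
    assert "F001" in str(err.value)
    assert sheet.sample_ids[2] in str(err.value)


def test_missing_manifest_probe_classed_intergenic(tmp_path):
    write_toy_cohort(tmp_path)
    manifest = fio.read_manifest_tsv(tmp_path / "manifest.tsv")
    fio.write_manifest_tsv(
        fio.ProbeManifest(manifest.frame.iloc[1:]), tmp_path / "manifest.tsv")
    bundle = fio.read_cohort(tmp_path / "expression.tsv", tmp_path / "beta.tsv",
                             tmp_path / "manifest.tsv", tmp_path / "samples.tsv")
    ann = bundle.manifest.annotation_for(bundle.beta.feature_ids[0])
    assert ann["gene_region"] == "intergenic"
    assert ann["island_region"] == "OpenSea"


def test_matrix_with_unknown_sample_names_file(tmp_path):
    write_toy_cohort(tmp_path)
    expr = fio.read_expression_tsv(tmp_path / "expression.tsv")
    frame = expr.to_frame()
    frame.columns = [*frame.columns[:-1], "GHOST_sample"]
    frame.index.name = "gene_id"
    frame.to_csv(tmp_path / "expression.tsv", sep="\t")
    with pytest.raises(FormatError, match="expression.tsv"):
        fio.read_cohort(tmp_path / "expression.tsv", tmp_path / "beta.tsv",
                        tmp_path / "manifest.tsv", tmp_path / "samples.tsv")


def test_loader_preserves_sheet_order(tmp_path):
    sheet, expr, *_ = write_toy_cohort(tmp_path)
    # shuffle matrix columns on disk; loader must realign to sheet order
    frame = expr.to_frame()[list(reversed(expr.sample_ids))]
    frame.index.name = "gene_id"
    frame.to_csv(tmp_path / "expression.tsv", sep="\t")
    bundle = fio.read_cohort(tmp_path / "expression.tsv", tmp_path / "beta.tsv",
                             tmp_path / "manifest.tsv", tmp_path / "samples.tsv")
    assert list(bundle.expression.sample_ids) == sheet.sample_ids
    assert bundle.expression == expr


def test_sample_sheet_invariants():
    sheet = make_sample_sheet(2)
    dup = pd.concat([sheet.frame, sheet.frame.iloc[[0]]])
    with pytest.raises(ValidationError, match="duplicate sample_id"):
        fio.SampleSheet(dup)
    bad = sheet.frame.copy()
    bad.loc[0, "group"] = "XXX"
    with pytest.raises(ValidationError, match="group"):
        fio.SampleSheet(bad)


@settings(max_examples=20, deadline=None)
@given(st.integers(1, 6), st.integers(1, 5), st.integers(0, 10_000))
def test_matrix_round_trip_property(tmp_path_factory, n_feat, n_samp, seed):
    rng = np.random.default_rng(seed)
    matrix = fio.ExpressionMatrix(
        tuple(f"F{i}" for i in range(n_feat)),
        tuple(f"S{j}" for j in range(n_samp)),
        rng.normal(0, 3, (n_feat, n_samp)))
    path = tmp_path_factory.mktemp("rt") / "m.tsv"
    fio.write_matrix_tsv(matrix, path, header={"seed": seed})
    assert fio.read_matrix_tsv(path, fio.ExpressionMatrix) == matrix


# ---------------------------------------------------------------------------
# GMT / PFM / FASTA
# ---------------------------------------------------------------------------

def test_gmt_basic_line(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("S1\tdesc\tG1\tG2\n")
    coll = fio.read_gmt(path)
    assert coll["S1"].members == frozenset({"G1", "G2"})


def test_gmt_round_trip(tmp_path):
    coll = fio.GeneSetCollection.from_sets([
        fio.GeneSet("A", "first", frozenset({"G1", "G2"})),
        fio.GeneSet("B", "second", frozenset({"G3"})),
    ])
    path = tmp_path / "sets.gmt"
    fio.write_gmt(coll, path)
    back = fio.read_gmt(path)
    assert {k: v.members for k, v in back.items()} == \
        {k: v.members for k, v in coll.items()}


def test_gmt_too_few_columns(tmp_path):
    path = tmp_path / "bad.gmt"
    path.write_text("S1\tdesc\n")
    with pytest.raises(FormatError):
        fio.read_gmt(path)


def test_jaspar_pfm_consensus(tmp_path):
    path = tmp_path / "m.pfm"
    path.write_text(">M1\nA [ 1 0 ]\nC [ 0 1 ]\nG [ 0 0 ]\nT [ 0 0 ]\n")
    motif = fio.read_jaspar_pfm(path)
    assert motif.length == 2
    assert motif.consensus == "AC"


def test_jaspar_pfm_wrong_row_count(tmp_path):
    path = tmp_path / "bad.pfm"
    path.write_text(">M1\nA [ 1 0 ]\nC [ 0 1 ]\nG [ 0 0 ]\n")
    with pytest.raises(FormatError):
        fio.read_jaspar_pfm(path)


def test_jaspar_round_trip(tmp_path):
    motif = fio.MotifModel("M2", np.array([[3, 0, 1], [1, 5, 0],
                                           [0, 1, 7], [2, 0, 0]], float))
    path = tmp_path / "m.pfm"
    fio.write_jaspar_pfm(motif, path)
    back = fio.read_jaspar_pfm(path)
    assert back.name == motif.name
    assert np.array_equal(back.counts, motif.counts)


def test_fasta_promoters(tmp_path):
    rng = np.random.default_rng(0)
    promoters = {f"G{i}": "".join(rng.choice(list("ACGT"), 1000))
                 for i in range(3)}
    path = tmp_path / "p.fasta"
    fio.write_fasta_promoters(promoters, path)
    back = fio.read_fasta_promoters(path)
    assert back == promoters
    assert all(len(s) == 1000 for s in back.values())


def test_fasta_duplicate_symbol(tmp_path):
    path = tmp_path / "dup.fasta"
    path.write_text(">G1\nACGT\n>G1\nTTTT\n")
    with pytest.raises(FormatError, match="G1"):
        fio.read_fasta_promoters(path)


# ---------------------------------------------------------------------------
# dynamics report
# ---------------------------------------------------------------------------

HEADER = "\t".join(fio.DYNAMICS_REPORT_COLUMNS)
ROW = ("cg05133314\t1\tGPR153\tTSS1500\tS_Shore\t11.0\t1.0\t10.0\t1.0\t-1.0"
       "\t0.0040\t0.0427\t10.6\t1.3\t12.6\t2.9\t2.0\t0.0107\t0.0432")


def test_parse_dynamics_report_row(tmp_path):
    path = tmp_path / "report.tsv"
    path.write_text(HEADER + "\n" + ROW + "\n")
    pairs = fio.parse_dynamics_report(path)
    assert len(pairs) == 1
    rec = pairs[0].ngt
    assert rec.mean_myoblast == 11.0 and rec.mean_myotube == 10.0
    assert rec.difference == -1.0
    assert pairs[0].t2d.q == 0.0432


def test_parse_dynamics_report_empty(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text(HEADER + "\n")
    assert fio.parse_dynamics_report(path) == []


def test_parse_dynamics_report_missing_q(tmp_path):
    row = ROW.rsplit("\t", 1)[0] + "\t"
    path = tmp_path / "bad.tsv"
    path.write_text(HEADER + "\n" + row + "\n")
    with pytest.raises(FormatError, match="cg05133314"):
        fio.parse_dynamics_report(path)


def test_parse_dynamics_report_non_numeric(tmp_path):
    row = ROW.replace("0.0427", "oops")
    path = tmp_path / "bad2.tsv"
    path.write_text(HEADER + "\n" + row + "\n")
    with pytest.raises(FormatError, match="ngt_q"):
        fio.parse_dynamics_report(path)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def test_load_config_flat(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("seed: 3\nn_genes: 100\n")
    assert fio.load_config(path) == {"seed": 3, "n_genes": 100}


def test_load_config_rejects_nested(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("block:\n  a: 1\n")
    with pytest.raises(FormatError):
        fio.load_config(path)
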