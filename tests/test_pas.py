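"""PAS engine: reference, CNR/BTIF, scoring, algebraic properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasqc.pas import (
    BTIFParams,
    PASError,
    PASMatrix,
    build_reference,
    compute_btif,
    compute_cnr,
    compute_pas,
    compute_pas_matrix,
    read_pas_tsv,
    write_pas_tsv,
)
from pasqc.pathway_db import GeneRole, Pathway, PathwayDB

from conftest import random_db, random_matrix


class TestReference:
    def test_log_mean_is_geometric_mean(self, tiny_matrix):
        m = tiny_matrix
        ref = build_reference(m, ["CTRL1", "CASE1"])
        # G1: 10 and 20 -> geometric mean sqrt(200)
        assert np.isclose(10 ** ref.log_mean["G1"], np.sqrt(200.0))

    def test_single_control_sd_zero(self, tiny_matrix):
        ref = build_reference(tiny_matrix, ["CTRL1"])
        assert (ref.log_sd == 0).all()

    def test_leave_one_out_requires_two_controls(self, tiny_matrix):
        with pytest.raises(PASError):
            build_reference(tiny_matrix, ["CTRL1"], policy="leave_one_out")

    def test_unknown_control_rejected(self, tiny_matrix):
        with pytest.raises(PASError, match="unknown control"):
            build_reference(tiny_matrix, ["NOPE"])


class TestBTIF:
    def test_band_is_max_of_ksd_and_floor(self):
        ref_mean = pd.Series({"G1": 1.0, "G2": 1.0})
        ref_sd = pd.Series({"G1": 0.0, "G2": 0.2})
        from pasqc.pas import ReferenceModel

        ref = ReferenceModel(ref_mean, ref_sd, ("C1", "C2"))
        params = BTIFParams(k=2.0, floor=0.1)
        # G1 band = max(0, 0.1) = 0.1; G2 band = max(0.4, 0.1) = 0.4
        case = pd.Series({"G1": 10 ** 1.2, "G2": 10 ** 1.2})
        flags = compute_btif(case, ref, params)
        assert flags["G1"] == 1  # |0.2| > 0.1
        assert flags["G2"] == 0  # |0.2| <= 0.4

    def test_boundary_is_exclusive(self):
        from pasqc.pas import ReferenceModel

        ref = ReferenceModel(
            pd.Series({"G1": 1.0}), pd.Series({"G1": 0.0}), ("C1",)
        )
        case = pd.Series({"G1": 10 ** 1.1})
        # set floor to the exact observed |log-ratio|: strict > must not flag
        floor = float(abs(np.log10(case["G1"]) - 1.0))
        assert compute_btif(case, ref, BTIFParams(floor=floor))["G1"] == 0
        assert compute_btif(case, ref, BTIFParams(floor=floor * 0.999))["G1"] == 1

    def test_negative_params_rejected(self):
        with pytest.raises(PASError):
            BTIFParams(k=-1.0)
        with pytest.raises(PASError):
            BTIFParams(floor=-0.1)


class TestComputePas:
    def test_hand_computed_example(self, tiny_matrix, tiny_db):
        # Reference CTRL1/CTRL2 identical -> SD 0, band = floor = 0.1.
        ref = build_reference(tiny_matrix, ["CTRL1", "CTRL2"])
        # CASE1: G1 20 vs 10 (lg 0.301, flagged), G2 unchanged.
        pas = compute_pas(tiny_matrix.data["CASE1"], tiny_db["P1"], ref)
        assert np.isclose(pas, 1.0 * np.log10(2.0))
        # CASE2 on P2: G3 40 vs 10 (lg 0.602, arr 0.5), G4 unchanged.
        pas2 = compute_pas(tiny_matrix.data["CASE2"], tiny_db["P2"], ref)
        assert np.isclose(pas2, 0.5 * np.log10(4.0))

    def test_within_band_genes_contribute_zero(self, tiny_matrix, tiny_db):
        ref = build_reference(tiny_matrix, ["CTRL1", "CTRL2"])
        case = tiny_matrix.data["CTRL1"] * 1.05  # lg 0.021 < floor 0.1
        assert compute_pas(case, tiny_db["P1"], ref) == 0.0

    def test_missing_gene_warn_and_strict(self, tiny_matrix):
        ref = build_reference(tiny_matrix, ["CTRL1", "CTRL2"])
        pw = Pathway("PX", [GeneRole("G1", 1.0), GeneRole("NOPE", 1.0)])
        with pytest.warns(UserWarning, match="missing"):
            compute_pas(tiny_matrix.data["CASE1"], pw, ref)
        with pytest.raises(PASError, match="missing"):
            compute_pas(
                tiny_matrix.data["CASE1"], pw, ref, missing_genes="strict"
            )

    def test_cnr_of_reference_line_pooled_is_not_one_but_loo_handles(self):
        # sanity: a control line differs from the pooled reference that
        # contains it, motivating the leave-one-out policy below
        data = pd.DataFrame(
            {"C1": [10.0], "C2": [40.0]}, index=["G1"]
        )
        from pasqc.expression import ExpressionMatrix

        m = ExpressionMatrix(data)
        ref = build_reference(m, ["C1", "C2"])
        cnr = compute_cnr(m.data["C1"], ref)
        assert not np.isclose(cnr["G1"], 1.0)


def _naive_pas_matrix(matrix, db, controls, params, policy):
    """Per-cell oracle: loops compute_pas over every (pathway, line)."""
    import warnings as _w

    pooled = build_reference(matrix, controls, "pooled")
    cols = {}
    for line in matrix.samples:
        if policy == "leave_one_out" and line in controls:
            rest = [c for c in controls if c != line]
            ref = build_reference(matrix, rest, "pooled")
        else:
            ref = pooled
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            cols[line] = [
                compute_pas(matrix.data[line], db[name], ref, params)
                for name in db.names
            ]
    return pd.DataFrame(cols, index=pd.Index(db.names, name="pathway"))


class TestComputePasMatrix:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_per_cell_oracle(self, seed):
        rng = np.random.default_rng(seed)
        db = random_db(rng, n_pathways=3, max_genes=5)
        genes = sorted(db.all_genes())
        m = random_matrix(rng, genes, 5)
        controls = list(m.samples[:2])
        params = BTIFParams(k=2.0, floor=0.1)
        for policy in ("pooled", "leave_one_out"):
            fast = compute_pas_matrix(m, db, controls, params, policy=policy)
            slow = _naive_pas_matrix(m, db, controls, params, policy)
            assert np.allclose(
                fast.data.to_numpy(), slow.to_numpy(), rtol=1e-12, atol=1e-12
            )

    def test_zero_at_reference(self):
        # every case column equal to the (identical) controls scores 0
        rng = np.random.default_rng(7)
        db = random_db(rng, n_pathways=3, max_genes=6)
        genes = sorted(db.all_genes())
        base = np.power(10.0, rng.normal(2, 0.5, len(genes)))
        data = pd.DataFrame(
            {s: base for s in ["C1", "C2", "X1", "X2"]}, index=genes
        )
        from pasqc.expression import ExpressionMatrix

        pas = compute_pas_matrix(
            ExpressionMatrix(data), db, ["C1", "C2"], policy="pooled"
        )
        assert np.allclose(pas.data.to_numpy(), 0.0)

    def test_global_scale_invariance(self):
        rng = np.random.default_rng(11)
        db = random_db(rng, n_pathways=3, max_genes=6)
        genes = sorted(db.all_genes())
        m = random_matrix(rng, genes, 5)
        from pasqc.expression import ExpressionMatrix

        scaled = ExpressionMatrix(m.data * 7.0)
        controls = list(m.samples[:2])
        a = compute_pas_matrix(m, db, controls)
        b = compute_pas_matrix(scaled, db, controls)
        assert np.allclose(a.data.to_numpy(), b.data.to_numpy(), rtol=1e-12)

    def test_arr_negation_antisymmetry(self):
        rng = np.random.default_rng(13)
        db = random_db(rng, n_pathways=3, max_genes=6)
        flipped = PathwayDB(
            [
                Pathway(p.name, [GeneRole(g.gene, -g.arr) for g in p.members])
                for p in db
            ]
        )
        genes = sorted(db.all_genes())
        m = random_matrix(rng, genes, 5)
        controls = list(m.samples[:2])
        a = compute_pas_matrix(m, db, controls)
        b = compute_pas_matrix(m, flipped, controls)
        assert np.allclose(a.data.to_numpy(), -b.data.to_numpy(), rtol=1e-12)

    def test_disjoint_union_additivity(self):
        rng = np.random.default_rng(17)
        db = random_db(rng, n_pathways=2, max_genes=6)
        p1, p2 = list(db)
        union = PathwayDB(
            [Pathway("U", list(p1.members) + list(p2.members))]
        )
        genes = sorted(db.all_genes())
        m = random_matrix(rng, genes, 4)
        controls = list(m.samples[:2])
        parts = compute_pas_matrix(m, db, controls)
        whole = compute_pas_matrix(m, union, controls)
        assert np.allclose(
            whole.data.loc["U"].to_numpy(),
            (parts.data.loc[p1.name] + parts.data.loc[p2.name]).to_numpy(),
            rtol=1e-12,
        )

    def test_leave_one_out_differs_for_controls_only(self):
        rng = np.random.default_rng(19)
        db = random_db(rng, n_pathways=3, max_genes=6)
        genes = sorted(db.all_genes())
        m = random_matrix(rng, genes, 6)
        controls = list(m.samples[:3])
        pooled = compute_pas_matrix(m, db, controls, policy="pooled")
        loo = compute_pas_matrix(m, db, controls, policy="leave_one_out")
        cases = [s for s in m.samples if s not in controls]
        assert np.allclose(
            pooled.data[cases].to_numpy(), loo.data[cases].to_numpy()
        )
        assert not np.allclose(
            pooled.data[controls].to_numpy(), loo.data[controls].to_numpy()
        )


class TestPASMatrixIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(23)
        data = pd.DataFrame(
            rng.normal(size=(3, 2)),
            index=["P1", "P2", "P3"],
            columns=["L1", "L2"],
        )
        pas = PASMatrix(data)
        path = tmp_path / "pas.tsv"
        write_pas_tsv(pas, path)
        back = read_pas_tsv(path)
        assert np.allclose(back.data.to_numpy(), data.to_numpy())
        assert list(back.pathways) == ["P1", "P2", "P3"]

    def test_non_finite_rejected(self):
        with pytest.raises(PASError, match="finite"):
            PASMatrix(pd.DataFrame({"L1": [np.nan]}, index=["P1"]))

    def test_subset_lines_unknown_rejected(self):
        pas = PASMatrix(pd.DataFrame({"L1": [0.0]}, index=["P1"]))
        with pytest.raises(PASError):
            pas.subset_lines(["L2"])
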