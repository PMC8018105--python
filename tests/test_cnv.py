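import numpy as np
import pandas as pd
import pytest

from epirelapse.errors import ValidationError
from epirelapse.cnv import (
    CnvMatrix,
    cnv_report,
    patient_logfc,
    subgroup_summary,
    top_k_loci,
    total_intensity,
)
from epirelapse.diffmeth import Pair, make_pairs
from epirelapse.io_model import (
    IntensityMatrices,
    ProbeAnnotation,
    SampleSheet,
    align_inputs,
)
from epirelapse.synthetic import CnaEvent, SimulationConfig, simulate_dataset


def _annotation(n, chrom="chr1"):
    return ProbeAnnotation(
        pd.DataFrame(
            {"chromosome": chrom, "position": range(1, n + 1), "substructure": "ISLAND"},
            index=pd.Index([f"cg{i}" for i in range(n)], name="probe_id"),
        )
    )


def _totals(data, samples):
    return pd.DataFrame(
        data, index=pd.Index([f"cg{i}" for i in range(len(data))], name="probe_id"),
        columns=samples,
    )


PAIR = Pair("p1", "prim", ("rel",), "g")


class TestTotalIntensity:
    def test_sum_of_channels(self):
        idx = pd.Index(["cg1"], name="probe_id")
        intens = IntensityMatrices(
            pd.DataFrame({"s1": [300.0]}, index=idx),
            pd.DataFrame({"s1": [700.0]}, index=idx),
        )
        assert total_intensity(intens).loc["cg1", "s1"] == 1000.0

    def test_channel_swap_symmetry(self):
        idx = pd.Index(["cg1", "cg2"], name="probe_id")
        m = pd.DataFrame({"s1": [10.0, 0.0]}, index=idx)
        u = pd.DataFrame({"s1": [5.0, 0.0]}, index=idx)
        a = total_intensity(IntensityMatrices(m, u))
        b = total_intensity(IntensityMatrices(u, m))
        pd.testing.assert_frame_equal(a, b)

    def test_negative_rejected_at_construction(self):
        idx = pd.Index(["cg1"], name="probe_id")
        with pytest.raises(ValidationError):
            IntensityMatrices(
                pd.DataFrame({"s1": [-1.0]}, index=idx),
                pd.DataFrame({"s1": [1.0]}, index=idx),
            )


class TestPatientLogfc:
    def test_identical_intensities_give_zero(self):
        totals = _totals(np.full((10, 2), 500.0), ["prim", "rel"])
        mat = patient_logfc(totals, [PAIR], _annotation(10))
        assert (mat.values.to_numpy() == 0).all()

    def test_doubled_relapse_centering_contract(self):
        totals = _totals(
            np.column_stack([np.full(10, 500.0), np.full(10, 1000.0)]), ["prim", "rel"]
        )
        centered = patient_logfc(totals, [PAIR], _annotation(10))
        assert centered.values.to_numpy() == pytest.approx(0.0, abs=1e-12)
        raw = patient_logfc(totals, [PAIR], _annotation(10), center=False)
        assert raw.values.to_numpy() == pytest.approx(
            np.log2(1001.0 / 501.0), abs=1e-12
        )

    def test_antisymmetry_when_labels_swap(self):
        rng = np.random.default_rng(2)
        totals = _totals(rng.lognormal(7, 0.3, (30, 2)), ["prim", "rel"])
        fwd = patient_logfc(totals, [PAIR], _annotation(30), center=False)
        swapped = Pair("p1", "rel", ("prim",), "g")
        back = patient_logfc(totals, [swapped], _annotation(30), center=False)
        assert fwd.values.to_numpy() == pytest.approx(-back.values.to_numpy())

    def test_single_chromosome_gain_stands_out_after_centering(self):
        rng = np.random.default_rng(4)
        n = 2000
        base = rng.lognormal(np.log(2000), 0.25, (n, 2))
        gained = np.arange(n) < n // 10  # 10% of loci on the gained chromosome
        base[gained, 1] *= 2.0
        totals = _totals(base, ["prim", "rel"])
        mat = patient_logfc(totals, [PAIR], _annotation(n))
        vals = mat.values.iloc[:, 0]
        gained_ids = [f"cg{i}" for i in range(n // 10)]
        # median-centering shifts every locus by the same constant, so the
        # gained-vs-rest contrast is the centering-invariant quantity
        contrast = vals.loc[gained_ids].mean() - vals.drop(gained_ids).mean()
        assert contrast == pytest.approx(1.0, abs=0.05)
        # centering contract: the genome-wide median is exactly zero
        assert vals.median() == pytest.approx(0.0, abs=1e-12)

    def test_loci_sorted_by_genome_position(self):
        ann = ProbeAnnotation(
            pd.DataFrame(
                {
                    "chromosome": ["chr2", "chr1", "chr10"],
                    "position": [5, 9, 1],
                    "substructure": "ISLAND",
                },
                index=pd.Index(["cg0", "cg1", "cg2"], name="probe_id"),
            )
        )
        totals = _totals(np.full((3, 2), 100.0), ["prim", "rel"])
        mat = patient_logfc(totals, [PAIR], ann)
        assert list(mat.loci["chromosome"]) == ["chr1", "chr2", "chr10"]

    def test_no_pairs_rejected(self):
        totals = _totals(np.full((3, 1), 1.0), ["prim"])
        with pytest.raises(ValidationError):
            patient_logfc(totals, [], _annotation(3))


class TestTopKLoci:
    def _matrix(self, values):
        n = len(values)
        ann = _annotation(n)
        return CnvMatrix(ann.table[["chromosome", "position"]], pd.DataFrame(
            values, index=ann.probe_ids, columns=["p1", "p2"]
        ))

    def test_k_equal_to_all_returns_everything(self):
        mat = self._matrix(np.random.default_rng(0).normal(0, 1, (20, 2)))
        assert len(top_k_loci(mat, 20).values) == 20
        assert len(top_k_loci(mat, 50).values) == 20  # warns, returns all

    def test_planted_high_variance_locus_selected(self):
        vals = np.zeros((50, 2))
        vals[17] = [5.0, -5.0]
        mat = self._matrix(vals)
        assert list(top_k_loci(mat, 1).values.index) == ["cg17"]

    def test_tie_break_is_positional_and_stable(self):
        vals = np.ones((30, 2)) * [[1.0, -1.0]]
        mat = self._matrix(vals)
        first = top_k_loci(mat, 5).values.index
        second = top_k_loci(mat, 5).values.index
        assert list(first) == list(second)
        assert list(first) == [f"cg{i}" for i in range(5)]

    def test_selection_invariant_under_patient_permutation(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, (100, 4))
        ann = _annotation(100)
        cols = ["a", "b", "c", "d"]
        mat = CnvMatrix(
            ann.table[["chromosome", "position"]],
            pd.DataFrame(vals, index=ann.probe_ids, columns=cols),
        )
        perm = CnvMatrix(
            ann.table[["chromosome", "position"]],
            pd.DataFrame(vals, index=ann.probe_ids, columns=cols)[["c", "a", "d", "b"]],
        )
        assert set(top_k_loci(mat, 10).values.index) == set(top_k_loci(perm, 10).values.index)


class TestCnvReport:
    def test_null_dataset_mean_abs_logfc_near_zero(self):
        ds = simulate_dataset(SimulationConfig(n_probes=1500, seed=41))
        al = align_inputs(ds.annotation, ds.beta, ds.sheet, ds.intensities)
        pairs = make_pairs(al.sheet)
        mat = patient_logfc(total_intensity(al.intensities), pairs, al.annotation)
        summary, fig = cnv_report(mat, al.sheet)
        assert fig is None
        # lognormal intensity noise alone: |logFC| small but nonzero
        assert (summary["mean_abs_logfc"] < 0.5).all()
        assert (summary["mean_logfc"].abs() < 0.02).all()

    def test_planted_arm_gain_recovered_per_subgroup(self):
        """A 1.5x event in one subgroup shows up at ~log2(1.5) on the
        affected loci for that subgroup's patients (Monte Carlo)."""
        cfg = SimulationConfig(
            n_probes=12_000, subgroups=(("hit", 12), ("ctl", 8)),
            delta_island={}, delta_shelf={}, n_chromosomes=4,
            cna_events=(CnaEvent("hit", "chr1", 1, 100_000_000, 1.5),),
            seed=55,
        )
        ds = simulate_dataset(cfg)
        al = align_inputs(ds.annotation, ds.beta, ds.sheet, ds.intensities)
        pairs = make_pairs(al.sheet)
        mat = patient_logfc(total_intensity(al.intensities), pairs, al.annotation)
        affected = ds.truth.intensity_log2_factor["hit"] > 0
        hit_patients = [p.patient_id for p in pairs if p.subgroup == "hit"]
        hit_vals = mat.values[hit_patients]
        # affected-vs-unaffected contrast is invariant to per-patient centering
        contrast = (
            hit_vals.loc[affected[affected].index].to_numpy().mean()
            - hit_vals.loc[affected[~affected].index].to_numpy().mean()
        )
        assert contrast == pytest.approx(np.log2(1.5), abs=0.05)
        ctl_vals = mat.values[[p.patient_id for p in pairs if p.subgroup == "ctl"]]
        ctl_contrast = (
            ctl_vals.loc[affected[affected].index].to_numpy().mean()
            - ctl_vals.loc[affected[~affected].index].to_numpy().mean()
        )
        assert abs(ctl_contrast) < 0.05

    def test_single_patient_cohort_runs(self, tmp_path):
        ds = simulate_dataset(SimulationConfig(n_probes=300, subgroups=(("g", 1),), seed=9))
        al = align_inputs(ds.annotation, ds.beta, ds.sheet, ds.intensities)
        pairs = make_pairs(al.sheet)
        mat = patient_logfc(total_intensity(al.intensities), pairs, al.annotation)
        summary, fig = cnv_report(mat, al.sheet, tmp_path)
        assert len(summary) == 1 and mat.values.shape[1] == 1
        assert fig is not None and fig.exists()

    def test_empty_matrix_rejected(self):
        ann = _annotation(1)
        empty = CnvMatrix(
            ann.table[["chromosome", "position"]].iloc[0:0],
            pd.DataFrame(index=ann.probe_ids[0:0], columns=["p1"], dtype=float),
        )
        sheet = SampleSheet(
            pd.DataFrame(
                {"patient_id": ["p1"], "status": ["PRIMARY"], "relapse_index": [0], "subgroup": ["g"]},
                index=pd.Index(["s1"], name="sample_id"),
            )
        )
        with pytest.raises(ValidationError):
            cnv_report(empty, sheet)
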