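import numpy as np
import pandas as pd
import pytest

from radicc.features import FeatureId, FeatureTable
from radicc.model import (AgreementStudy, build_agreement_map,
                          discover_classes, metric_comparison_report,
                          partitions_equal, rate_against_reference,
                          screen_features)


def make_table(rng, n=10, segs=None, features=None):
    """Synthetic feature table with controllable per-feature behaviour.

    ``features`` maps FeatureId -> callable(subject_values, seg_index) giving
    the cell value; defaults build three features with high / medium / no
    inter-segmentation agreement.
    """
    segs = segs or [f"s{j}" for j in range(1, 5)]
    if features is None:
        base = rng.normal(size=n)
        features = {
            FeatureId("original", "firstorder", "Mean"):
                lambda b, j: b + rng.normal(0, 0.01, n),
            FeatureId("original", "glcm", "Contrast"):
                lambda b, j: b + rng.normal(0, 0.8, n),
            FeatureId("original", "ngtdm", "Busyness"):
                lambda b, j: rng.normal(0, 1.0, n),
        }
    else:
        base = rng.normal(size=n)
    tumors = [f"t{i}" for i in range(n)]
    rows = {}
    for j, s in enumerate(segs):
        for fid, gen in features.items():
            col = gen(base, j)
            for i, t in enumerate(tumors):
                rows.setdefault((t, s), {})[fid] = col[i]
    idx = pd.MultiIndex.from_tuples(rows, names=["tumor_id", "segmentation_id"])
    cols = pd.MultiIndex.from_tuples(
        features, names=["image_type", "feature_class", "feature_name"])
    data = pd.DataFrame([[rows[k][f] for f in features] for k in idx],
                        index=idx, columns=cols)
    return FeatureTable(data.sort_index())


class TestScreening:
    def test_band_semantics(self, rng):
        table = make_table(rng)
        report = screen_features(table, band=(-1.0, 1.0), n_select=2)
        iccs = report.icc_star["icc"]
        assert len(report.in_band) == 3  # every non-degenerate feature
        # tighten the band around the middle feature only
        mid = sorted(iccs)[1]
        tight = screen_features(table, band=(mid - 1e-6, mid + 1e-6))
        assert len(tight.in_band) == 1

    def test_selection_takes_lowest_icc_in_band(self, rng):
        table = make_table(rng)
        report = screen_features(table, band=(-1.0, 1.0), n_select=2)
        iccs = report.icc_star["icc"]
        expected = set(iccs.nsmallest(2).index)
        assert {tuple(f) for f in report.selected} == expected
        assert set(report.selected) <= set(report.in_band)

    def test_empty_band_warns_and_selects_nothing(self, rng):
        table = make_table(rng)
        with pytest.warns(UserWarning, match="band"):
            # ICC never exceeds 1, so this band is empty by construction
            report = screen_features(table, band=(1.5, 2.0))
        assert report.selected == []

    def test_explicit_selection_overrides_the_rule(self, rng):
        table = make_table(rng)
        fid = FeatureId("original", "ngtdm", "Busyness")
        report = screen_features(table, selected=[fid])
        assert report.selected == [fid]
        assert report.selection_rule == "explicit-list"

    def test_degenerate_features_are_excluded_and_listed(self, rng):
        fid_const = FeatureId("original", "shape", "VoxelVolume")
        feats = {
            fid_const: lambda b, j: np.full(len(b), 5.0),
            FeatureId("original", "firstorder", "Mean"):
                lambda b, j: b + rng.normal(0, 0.1, len(b)),
        }
        table = make_table(rng, features=feats)
        report = screen_features(table, band=(-1.0, 1.0))
        assert report.degenerate == [fid_const]
        assert fid_const not in report.in_band


class TestAgreementMap:
    def test_matrix_shape_and_conventions(self, rng):
        table = make_table(rng, segs=[f"s{j}" for j in range(1, 10)])
        fid = FeatureId("original", "firstorder", "Mean")
        amap = build_agreement_map(table, [fid])
        mat = amap.per_feature[fid]
        assert mat.shape == (9, 9)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)
        # 36 independent off-diagonal entries
        assert len(amap.results[fid]) == 36

    def test_identical_segmentations_give_all_ones(self, rng):
        base = rng.normal(size=8)
        feats = {FeatureId("original", "firstorder", "Mean"):
                 lambda b, j: b.copy()}
        table = make_table(rng, n=8, features=feats)
        amap = build_agreement_map(table, list(feats))
        np.testing.assert_allclose(
            amap.per_feature[list(feats)[0]].to_numpy(), 1.0)

    def test_relabeling_permutes_the_matrix(self, rng):
        table = make_table(rng)
        fid = FeatureId("original", "glcm", "Contrast")
        amap = build_agreement_map(table, [fid])
        perm = ["s3", "s1", "s4", "s2"]
        permuted_table = FeatureTable(
            table.data.reindex(
                pd.MultiIndex.from_product([table.tumor_ids, perm])))
        amap_p = build_agreement_map(permuted_table, [fid])
        np.testing.assert_allclose(
            amap_p.per_feature[fid].loc[perm, perm].to_numpy(),
            amap.per_feature[fid].loc[perm, perm].to_numpy(), atol=1e-12)


class TestDiscoverClasses:
    @staticmethod
    def _block_map(rng, within=0.9, cross=0.1):
        ids = [f"s{j}" for j in range(1, 10)]
        fid = FeatureId("original", "firstorder", "Mean")
        mat = pd.DataFrame(np.full((9, 9), cross), index=ids, columns=ids)
        for blk in (ids[0:3], ids[3:6], ids[6:9]):
            mat.loc[blk, blk] = within
        np.fill_diagonal(mat.to_numpy(), 1.0)
        from radicc.model import AgreementMap
        return AgreementMap({fid: mat}, {fid: {}}, ids)

    def test_block_structure_recovers_three_classes(self, rng):
        amap = self._block_map(rng)
        labels = discover_classes(amap, 3)
        truth = {f"s{j}": (j - 1) // 3 + 1 for j in range(1, 10)}
        assert partitions_equal(labels, truth)

    def test_single_class_groups_everything(self, rng):
        labels = discover_classes(self._block_map(rng), 1)
        assert set(labels.values()) == {1}

    def test_too_many_classes_is_config_error(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            discover_classes(self._block_map(rng), 10)

    def test_partitions_equal_ignores_label_names(self):
        a = {"x": 1, "y": 1, "z": 2}
        b = {"x": 9, "y": 9, "z": 4}
        c = {"x": 1, "y": 2, "z": 2}
        assert partitions_equal(a, b)
        assert not partitions_equal(a, c)


class TestReferenceRating:
    def test_identical_to_reference_is_concordant(self, rng):
        feats = {FeatureId("original", "firstorder", "Mean"):
                 lambda b, j: b.copy()}
        table = make_table(rng, features=feats)
        frame = rate_against_reference(table, list(feats), "s1")
        assert all(v == "concordant" for v in frame.attrs["verdicts"].values())
        np.testing.assert_allclose(frame.to_numpy(), 1.0)

    def test_noisy_rater_discordant_under_extreme_threshold(self, rng):
        table = make_table(rng)
        frame = rate_against_reference(table, table.feature_ids, "s1",
                                       threshold=1.0)
        # every non-identical segmentation has some ICC < 1
        assert all(v == "discordant" for v in frame.attrs["verdicts"].values())

    def test_unknown_reference_or_rule_rejected(self, rng):
        table = make_table(rng)
        with pytest.raises(ValueError, match="reference"):
            rate_against_reference(table, table.feature_ids, "nope")
        with pytest.raises(ValueError, match="rule"):
            rate_against_reference(table, table.feature_ids, "s1", rule="any")

    def test_output_has_table2_shape(self, rng):
        table = make_table(rng, segs=[f"s{j}" for j in range(1, 10)])
        frame = rate_against_reference(table, table.feature_ids, "s1")
        assert list(frame.columns) == [f"iccs1-s{j}" for j in range(2, 10)]
        assert len(frame) == 3  # one row per selected feature


class TestEndToEnd:
    def test_cohort_pipeline_on_identical_masks(self, rng, small_cohort):
        """Identical segmentations: geometry saturates and ICC is 1."""
        from radicc.features import extract_cohort
        from radicc.metrics import metrics_to_frame, pairwise_metrics
        from radicc.phantoms import DILATION, PerturbationFamily, make_cohort
        from radicc.phantoms import PhantomSpec

        spec = PhantomSpec(n_tumors=3, grid_shape=(48, 48, 48),
                           radius_range_mm=(14.0, 17.0), seed=9,
                           families=(PerturbationFamily(
                               "Z", DILATION, (0.0, 0.0, 0.0)),))
        cohort = make_cohort(spec)
        subset = [FeatureId("original", "firstorder", "Mean"),
                  FeatureId("original", "shape", "MeshVolume"),
                  FeatureId("original", "glszm", "GrayLevelVariance")]
        table = extract_cohort(cohort, subset=subset)
        rows = []
        for entry in cohort.tumors:
            rows.extend(pairwise_metrics(entry.segmentations, entry.tumor_id))
        metrics = metrics_to_frame(rows)
        assert (metrics["dsc"] == 1.0).all()
        assert (metrics["sdsc"] == 1.0).all()
        assert (metrics["hd_mm"] == 0.0).all()
        amap = build_agreement_map(table, subset)
        rep = metric_comparison_report(amap, metrics)
        finite = rep.scatter["icc"].dropna()
        np.testing.assert_allclose(finite, 1.0)

    def test_pair_set_mismatch_is_a_join_error(self, rng):
        table = make_table(rng)
        amap = build_agreement_map(
            table, [FeatureId("original", "firstorder", "Mean")])
        metrics = pd.DataFrame({"tumor_id": ["t0"], "seg_i": ["s1"],
                                "seg_j": ["s2"], "dsc": [1.0], "sdsc": [1.0],
                                "hd_mm": [0.0]})
        with pytest.raises(ValueError, match="pairs"):
            metric_comparison_report(amap, metrics)

    def test_model_fit_summary_and_tables(self, rng, small_cohort):
        study = AgreementStudy.from_cohort(small_cohort, band=(-1.0, 1.0),
                                           n_select=4)
        res = study.fit()
        assert len(res.icc_star_table) == 944
        sel = res.selected_table()
        assert len(sel) == 4
        assert {"icc_star", "icc_average", "icc_min", "lower",
                "upper"} <= set(sel.columns)
        text = res.summary()
        assert "selected: 4" in text and "944" in text
        classes = res.discover_classes(3)
        assert set(classes) == set(small_cohort.segmentation_ids)
        rep = res.metric_comparison()
        assert rep.summary["n_pairs"] == 36
        assert len(rep.scatter) == 4 * 36

    def test_feature_table_csv_round_trip(self, rng, tmp_path):
        table = make_table(rng)
        path = tmp_path / "features.csv"
        table.to_csv(path)
        back = FeatureTable.from_csv(path)
        assert back.segmentation_ids == table.segmentation_ids
        np.testing.assert_allclose(
            back.data.to_numpy(), table.data.loc[back.data.index,
                                                 back.data.columns].to_numpy())
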