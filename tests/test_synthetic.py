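"""Generator contracts: study shape, planted-effect fidelity, QC stability,
determinism and CSV round-tripping."""

import numpy as np
import pandas as pd
import pytest

from metaboeval.synthetic import (
    PerturbationSpec,
    StudyDesign,
    generate_study,
    read_study,
    write_study,
)


class TestDesignValidation:
    def test_default_matches_six_group_design(self):
        d = StudyDesign()
        assert d.n_animals == 63
        assert d.days == (-1, 1, 4, 7, 10)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_per_group=(0, 1, 1, 1, 1, 1)),
            dict(days=(1, 1, 4)),
            dict(days=(4, 1)),
            dict(control_group="missing"),
            dict(n_qc=0),
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StudyDesign(**kwargs)

    def test_invalid_spec_rejected(self):
        d = StudyDesign()
        with pytest.raises(ValueError):
            PerturbationSpec(n_perturbed=500).validate(d)
        with pytest.raises(ValueError):
            PerturbationSpec(
                group_attenuation={**dict.fromkeys(d.groups, 0.5), "C": 0.0, "T": 1.5}
            ).validate(d)
        with pytest.raises(ValueError):
            # control attenuation must be zero
            s = PerturbationSpec()
            s.group_attenuation["C"] = 0.3
            s.validate(d)
        with pytest.raises(ValueError):
            # profile must vanish at baseline
            s = PerturbationSpec()
            s.effect_profile[-1] = 0.5
            s.validate(d)


class TestGeneratedStructure:
    def test_shape_counts(self, study):
        table, phenotypes, truth = study
        meta = table.sample_meta
        per_day = meta[meta.sample_type == "study"].groupby("day").size()
        assert (per_day == 63).all()
        assert len(table.qc_ids) == 10 and len(table.blank_ids) == 4
        assert len(phenotypes) == 63 * 5

    def test_intensities_positive_where_observed(self, study):
        table, _, _ = study
        vals = table.intensities.to_numpy()
        assert np.nanmin(vals) > 0

    def test_exogenous_absent_outside_own_group(self, study):
        table, _, truth = study
        meta = table.sample_meta
        for g, ids in truth.exogenous_feature_ids.items():
            others = meta.index[
                (meta.sample_type == "study") & (meta.group != g)
            ]
            assert table.intensities.loc[others, ids].isna().all().all()
            own_post = meta.index[
                (meta.sample_type == "study") & (meta.group == g) & (meta.day > -1)
            ]
            obs_frac = table.intensities.loc[own_post, ids].notna().mean().mean()
            assert obs_frac > 0.95

    def test_blanks_background_only(self, study):
        table, _, truth = study
        blanks = table.intensities.loc[table.blank_ids]
        non_bg = [f for f in table.feature_ids if f not in truth.background_feature_ids]
        assert blanks[non_bg].isna().all().all()
        assert blanks[truth.background_feature_ids].notna().all().all()

    def test_control_deregulation_zero(self, study):
        table, _, truth = study
        meta = table.sample_meta
        ctrl = meta.index[(meta.sample_type == "study") & (meta.group == "C")]
        assert (truth.deregulation.loc[ctrl] == 0).all()

    def test_qc_rsd_below_configured_bound(self, study):
        """QC analytical noise of 0.1 log2 keeps feature RSDs ~7%, below 15%."""
        table, _, _ = study
        qc = table.intensities.loc[table.qc_ids]
        well_observed = qc.columns[qc.notna().all()]
        rsd = qc[well_observed].std(ddof=1) / qc[well_observed].mean()
        assert rsd.median() < 0.15

    def test_phenotypes_monotone_in_deregulation(self, study):
        table, phenotypes, truth = study
        meta = table.sample_meta.loc[table.study_ids]
        dereg = truth.deregulation.groupby(
            [meta["animal_id"], meta["day"]]
        ).first()
        merged = phenotypes.set_index(["animal_id", "day"]).join(
            dereg.rename("m")
        )
        # strong positive DS / negative RBW relation with true deregulation
        assert merged["ds"].corr(merged["m"]) > 0.8
        assert merged["rbw"].corr(merged["m"]) < -0.8


class TestPlantedEffects:
    def test_day4_fold_change_matches_planted_delta(self):
        """Observed T-vs-C day-4 log2 fold change ≈ planted effect per feature."""
        table, _, truth = generate_study(seed=21)
        lt = np.log2(table.intensities.loc[table.group_sample_ids("T", 4)])
        lc = np.log2(table.intensities.loc[table.group_sample_ids("C", 4)])
        fc = (lt.mean() - lc.mean())[truth.perturbed_feature_ids]
        planted = pd.Series(truth.effect_log2)
        err = fc - planted
        # Monte-Carlo error: sd 0.47/sqrt(10)+0.47/sqrt(11) per feature
        assert err.abs().mean() < 0.25
        assert fc.corr(planted) > 0.98

    def test_flat_profile_gives_null_group_differences(self):
        """With effect_profile ≡ 0 groups are exchangeable: ~nominal rejections."""
        from metaboeval.stats import mann_whitney

        spec = PerturbationSpec(effect_profile=dict.fromkeys((-1, 1, 4, 7, 10), 0.0))
        table, _, truth = generate_study(spec=spec, seed=3)
        ids_t = table.group_sample_ids("T", 4)
        ids_c = table.group_sample_ids("C", 4)
        lt = table.intensities.loc[ids_t]
        lc = table.intensities.loc[ids_c]
        feats = [f for f in truth.perturbed_feature_ids]
        ps = [
            mann_whitney(lt[f].dropna(), lc[f].dropna()).p_value for f in feats
        ]
        rate = np.mean(np.array(ps) < 0.05)
        assert rate < 0.2  # ~5% nominal, generous Monte-Carlo margin

    def test_attenuation_orders_group_deviation(self):
        """Expected day-4 deviation of group means from control follows attenuation."""
        devs = {g: [] for g in ("T/HQD", "T/SS", "T/BB", "T/SF", "T")}
        for seed in range(4):
            table, _, truth = generate_study(seed=seed)
            lc = np.log2(
                table.intensities.loc[table.group_sample_ids("C", 4),
                                      truth.perturbed_feature_ids]
            ).mean()
            for g in devs:
                lg = np.log2(
                    table.intensities.loc[table.group_sample_ids(g, 4),
                                          truth.perturbed_feature_ids]
                ).mean()
                devs[g].append((lg - lc).abs().mean())
        means = {g: np.mean(v) for g, v in devs.items()}
        assert (
            means["T/HQD"] < means["T/SS"] < means["T/BB"] < means["T/SF"] < means["T"]
        )


class TestDeterminismAndIO:
    def test_same_seed_bitwise_identical(self):
        t1, p1, g1 = generate_study(seed=77)
        t2, p2, g2 = generate_study(seed=77)
        assert t1.equals(t2)
        assert p1.equals(p2)
        assert g1.perturbed_feature_ids == g2.perturbed_feature_ids
        t3, _, _ = generate_study(seed=78)
        assert not t1.intensities.equals(t3.intensities)

    def test_roundtrip_identity(self, tmp_path, study):
        table, phenotypes, truth = study
        write_study(table, phenotypes, truth, tmp_path)
        t2, p2, g2 = read_study(tmp_path)
        pd.testing.assert_frame_equal(table.intensities, t2.intensities)
        pd.testing.assert_frame_equal(table.sample_meta, t2.sample_meta)
        pd.testing.assert_frame_equal(
            phenotypes.reset_index(drop=True), p2.reset_index(drop=True)
        )
        assert g2.perturbed_feature_ids == truth.perturbed_feature_ids
        assert g2.exogenous_feature_ids == truth.exogenous_feature_ids

    def test_missing_read_back_as_missing_not_zero(self, tmp_path, study):
        table, phenotypes, truth = study
        write_study(table, phenotypes, truth, tmp_path)
        t2, _, _ = read_study(tmp_path)
        assert t2.intensities.isna().sum().sum() == table.intensities.isna().sum().sum()
        assert (t2.intensities == 0).sum().sum() == 0

    def test_duplicate_sample_id_rejected(self, tmp_path, study):
        table, phenotypes, truth = study
        write_study(table, phenotypes, truth, tmp_path)
        path = tmp_path / "intensities.csv"
        lines = path.read_text().splitlines()
        lines.append(lines[1])  # duplicate first sample row
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="duplicat"):
            read_study(tmp_path)

    def test_unknown_sample_type_rejected(self, tmp_path, study):
        table, phenotypes, truth = study
        write_study(table, phenotypes, truth, tmp_path)
        path = tmp_path / "samples.csv"
        txt = path.read_text().replace("study", "mystery", 1)
        path.write_text(txt)
        with pytest.raises(ValueError, match="sample_type"):
            read_study(tmp_path)
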