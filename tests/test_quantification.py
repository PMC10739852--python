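"""Well summaries, compound categorization, dose-response, intensity tests."""

import numpy as np
import pandas as pd
import pytest

from pgccscope.quantify import (
    DoseResponse,
    compare_conditions,
    compare_intensity,
    fit_dose_response,
    four_param_logistic,
    process_plate,
    summarize_well,
)
from pgccscope.simulate import (
    PlateCondition,
    SimParams,
    simulate_count_screen,
    simulate_plate,
)


def records_with_classes(classes):
    n = len(classes)
    viability = ["dead" if c == "dead" else ("unassigned" if c == "debris" else "live") for c in classes]
    ploidy = ["unassigned" if c == "dead" else c for c in classes]
    return pd.DataFrame(
        {
            "field_id": ["f"] * n,
            "label": np.arange(1, n + 1),
            "area_px": np.full(n, 100),
            "mean_ros": np.nan,
            "viability": viability,
            "ploidy_class": ploidy,
        }
    )


class TestSummarizeWell:
    def test_counts_by_class(self):
        s = summarize_well(records_with_classes(["pgcc", "pgcc", "non_pgcc", "dead"]))
        assert (s.n_non_pgcc, s.n_pgcc, s.n_dead, s.n_debris) == (1, 2, 1, 0)
        assert s.pgcc_fraction == pytest.approx(2 / 3)

    def test_empty_records(self):
        s = summarize_well(records_with_classes([]))
        assert (s.n_non_pgcc, s.n_pgcc, s.n_dead, s.n_debris) == (0, 0, 0, 0)
        assert np.isnan(s.pgcc_fraction)

    def test_unassigned_records_rejected(self):
        rec = records_with_classes(["non_pgcc"])
        rec.loc[0, "viability"] = "unassigned"
        with pytest.raises(ValueError, match="gating"):
            summarize_well(rec)
        rec = records_with_classes(["non_pgcc"])
        rec.loc[0, "ploidy_class"] = "unassigned"
        with pytest.raises(ValueError, match="classification"):
            summarize_well(rec)

    def test_matches_ground_truth_on_simulated_well(
        self, default_truth, classified_records
    ):
        s = summarize_well(classified_records)
        counts = default_truth["class"].value_counts()
        assert s.n_non_pgcc == counts["non_pgcc"]
        assert s.n_pgcc == counts["pgcc"]
        assert s.n_dead == counts["dead"]


def summary_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "well_id", "condition", "compound", "concentration", "replicate",
            "n_non_pgcc", "n_pgcc", "n_dead", "n_debris",
        ],
    )


def wells(condition, compound, non, pgcc):
    return [
        (f"{compound}-{i}", condition, compound, 1.0, i + 1, non[i], pgcc[i], 0, 0)
        for i in range(len(non))
    ]


class TestCompareConditions:
    def test_identical_counts_inactive_p_one(self):
        df = summary_frame(
            wells("ctrl", "ctrl", [100] * 3, [10] * 3)
            + wells("cpdA", "cpdA", [100] * 3, [10] * 3)
        )
        eff = compare_conditions(df, "ctrl")
        assert eff.category.iloc[0] == "inactive"
        assert eff.p_non_pgcc.iloc[0] == pytest.approx(1.0)

    def test_extreme_non_pgcc_kill(self):
        df = summary_frame(
            wells("ctrl", "ctrl", [100, 100, 100], [10, 11, 9])
            + wells("cpdA", "cpdA", [0, 0, 0], [10, 11, 9])
        )
        eff = compare_conditions(df, "ctrl")
        assert eff.category.iloc[0] == "kills_non_pgcc_only"

    def test_pgcc_induction(self):
        df = summary_frame(
            wells("ctrl", "ctrl", [100, 101, 99], [5, 6, 4])
            + wells("dtx", "dtx", [100, 101, 99], [60, 66, 58])
        )
        eff = compare_conditions(df, "ctrl")
        assert eff.category.iloc[0] == "induces_pgcc"

    def test_kills_both(self):
        df = summary_frame(
            wells("ctrl", "ctrl", [100, 101, 99], [50, 52, 48])
            + wells("x", "x", [10, 11, 9], [5, 6, 4])
        )
        eff = compare_conditions(df, "ctrl")
        assert eff.category.iloc[0] == "kills_both"

    def test_missing_control_rejected(self):
        df = summary_frame(wells("cpdA", "cpdA", [1, 2], [1, 2]))
        with pytest.raises(ValueError, match="control"):
            compare_conditions(df, "ctrl")

    def test_single_replicate_rejected(self):
        df = summary_frame(
            wells("ctrl", "ctrl", [100, 100], [10, 10]) + wells("cpdA", "cpdA", [50], [5])
        )
        with pytest.raises(ValueError, match="replicates"):
            compare_conditions(df, "ctrl")

    def test_planted_effect_recovery(self):
        """200 simulated compounds with 40 planted PGCC killers: >= 90%
        categorized as killing PGCCs, with per-compound fresh sampling."""
        mults = [0.1] * 40 + [1.0] * 160
        recovered = 0
        for i, m in enumerate(mults):
            df = simulate_count_screen(
                1, 3, 100.0, 20.0, seed=1000 + i, pgcc_mults=[m]
            )
            eff = compare_conditions(df, "control")
            if m < 1 and eff.category.iloc[0] in ("kills_pgcc_only", "kills_both"):
                recovered += 1
        assert recovered >= 0.9 * 40


class TestDoseResponse:
    def test_exact_recovery_noise_free(self):
        conc = np.array([0.01, 0.1, 1.0, 10.0, 100.0])
        resp = four_param_logistic(conc, top=1.0, bottom=0.0, ic50=1.0, hill=1.0)
        fit = fit_dose_response(conc, resp)
        assert fit.converged
        assert fit.ic50 == pytest.approx(1.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-4)
        assert fit.bottom <= fit.top

    def test_flat_response_not_converged(self):
        fit = fit_dose_response([0.01, 0.1, 1, 10], [1.0, 1.0, 1.0, 1.0])
        assert not fit.converged

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_dose_response([1, 2, 2, 1], [1, 0.5, 0.5, 1])

    def test_concentration_rescaling_scales_ic50(self):
        """Multiplying all concentrations by k multiplies the IC50 by k."""
        conc = np.geomspace(0.01, 100, 6)
        resp = four_param_logistic(conc, 1.0, 0.1, 0.5, 1.3)
        f1 = fit_dose_response(conc, resp)
        k = 37.0
        f2 = fit_dose_response(conc * k, resp)
        assert f2.ic50 == pytest.approx(f1.ic50 * k, rel=1e-4)

    def test_noisy_recovery(self, rng):
        """sigma=0.05 noise, 3 wells/dose: median |log10 IC50 error| < 0.15."""
        errs = []
        for _ in range(30):
            conc = np.geomspace(1e-3, 100, 8)
            c = np.repeat(conc, 3)
            r = four_param_logistic(c, 1.0, 0.0, 1.0, 1.0) + rng.normal(0, 0.05, len(c))
            fit = fit_dose_response(c, np.clip(r, 0, None))
            errs.append(abs(np.log10(fit.ic50)))
        assert np.median(errs) < 0.15

    def test_summary_contains_ic50(self):
        conc = np.geomspace(0.01, 100, 5)
        fit = DoseResponse(conc, four_param_logistic(conc, 1, 0, 1, 1)).fit()
        assert "IC50" in fit.summary()


class TestCompareIntensity:
    def _records(self, a_vals, b_vals):
        n = len(a_vals) + len(b_vals)
        return pd.DataFrame(
            {
                "mean_ros": np.concatenate([a_vals, b_vals]),
                "ploidy_class": ["pgcc"] * len(a_vals) + ["non_pgcc"] * len(b_vals),
            }
        )

    def test_identical_groups_p_near_one(self):
        vals = np.linspace(100, 200, 50)
        res = compare_intensity(self._records(vals, vals))
        assert res.pvalue > 0.95

    def test_separated_lognormals_significant(self, rng):
        a = rng.lognormal(np.log(1000), 0.3, 200)
        b = rng.lognormal(np.log(100), 0.3, 200)
        res = compare_intensity(self._records(a, b))
        assert res.pvalue < 1e-3
        assert res.median_fold > 5

    def test_empty_group_named(self):
        with pytest.raises(ValueError, match="pgcc"):
            compare_intensity(self._records([], [1.0, 2.0]))

    def test_mannwhitney_selectable(self, rng):
        a = rng.lognormal(7, 0.3, 50)
        b = rng.lognormal(5, 0.3, 50)
        res = compare_intensity(self._records(a, b), method="mannwhitney")
        assert res.pvalue < 1e-3


@pytest.fixture(scope="module")
def small_plate(tmp_path_factory):
    out = tmp_path_factory.mktemp("plate")
    base = SimParams(
        image_shape=(512, 512), n_non_pgcc=25, n_pgcc=6, n_dead=3, n_debris=3
    )
    conds = [
        PlateCondition(name="control", n_replicates=2),
        PlateCondition(
            name="treated", compound="cpdX", concentration=1e-6,
            n_replicates=2, pgcc_mult=0.1,
        ),
    ]
    simulate_plate(base, conds, "control", out, seed=9)
    return out


class TestProcessPlate:
    def test_four_well_plate_one_effect_row(self, small_plate, tmp_path):
        paths = process_plate(small_plate / "layout.yaml", small_plate, tmp_path / "res")
        eff = pd.read_csv(paths["effects"])
        assert len(eff) == 1
        assert eff.compound.iloc[0] == "cpdX"
        summaries = pd.read_csv(paths["summaries"])
        records = pd.read_csv(paths["records"])
        # count conservation: summary counts add up to classified records
        total = summaries[["n_non_pgcc", "n_pgcc", "n_dead", "n_debris"]].sum().sum()
        assert total == len(records)

    def test_rerun_byte_identical(self, small_plate, tmp_path):
        p1 = process_plate(small_plate / "layout.yaml", small_plate, tmp_path / "r1")
        p2 = process_plate(small_plate / "layout.yaml", small_plate, tmp_path / "r2")
        for key in ("records", "summaries", "effects"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_missing_image_fails_atomically(self, small_plate, tmp_path):
        """Deleting one image fails with the well named and leaves no
        partial outputs."""
        import shutil

        broken = tmp_path / "broken_plate"
        shutil.copytree(small_plate, broken)
        victim = next(broken.glob("*_nuclei.tif"))
        well = victim.name.split("_")[0]
        victim.unlink()
        outdir = tmp_path / "res"
        with pytest.raises(FileNotFoundError, match=well):
            process_plate(broken / "layout.yaml", broken, outdir)
        assert not outdir.exists() or not any(outdir.iterdir())
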