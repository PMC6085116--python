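import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from wristsim import Motion, angle_grid, generate_trajectory, peak_force, wilcoxon_signed_rank
from wristsim.controller import SimulationResult
from wristsim.errors import DegenerateSampleError, MissingSampleError, PairingError
from wristsim.specimens import MUSCLES
from wristsim.stats import compare_conditions, extract_grid_forces, extract_peaks, summarize_peaks
from wristsim.trajectories import GridPoint

from oracles import wilcoxon_asymptotic_closed_form, wilcoxon_exact_enumeration


def synthetic_result(motion, force_fn, cycles=3, condition="intact", specimen="s1"):
    """Build a SimulationResult whose forces follow ``force_fn(traj, muscle)``."""
    traj = generate_trajectory(motion, cycles=cycles)
    n = len(traj)
    forces = np.column_stack([force_fn(traj, m) for m in MUSCLES])
    postures = np.column_stack([traj.theta_fe, traj.theta_rud])
    return SimulationResult(
        motion=traj.motion,
        specimen_id=specimen,
        condition=condition,
        times=traj.times,
        postures=postures,
        target_postures=postures.copy(),
        torque_demands=np.zeros((n, 2)),
        forces=forces,
        tracking_error=np.zeros(n),
        infeasible_steps=0,
        cycle_boundaries=traj.cycle_boundaries,
        dt=traj.dt,
    )


# --------------------------------------------------------------------------
# Wilcoxon engine
# --------------------------------------------------------------------------


def test_all_zero_differences_is_degenerate():
    with pytest.raises(DegenerateSampleError):
        wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_seven_concordant_pairs_exact():
    x = np.zeros(7)
    y = np.arange(1.0, 8.0)
    res = wilcoxon_signed_rank(x, y, method="exact")
    assert res.w_statistic == 0
    assert res.p_value == pytest.approx(2 / 128)


def test_asymptotic_w0_at_n7_closed_form():
    x = np.zeros(7)
    y = np.arange(1.0, 8.0)
    res = wilcoxon_signed_rank(x, y, method="asymptotic")
    assert res.p_value == pytest.approx(2 * scipy.stats.norm.cdf(-14 / np.sqrt(35)), rel=1e-12)


@pytest.mark.parametrize("w,expected", [(0, 0.018), (1, 0.028), (2, 0.043), (3, 0.063)])
def test_asymptotic_p_vocabulary_at_n7(w, expected):
    """At n=7 without ties, W in {0..3} rounds to the familiar p-value set."""
    x = np.zeros(7)
    d = np.arange(1.0, 8.0)
    if w > 0:
        d[w - 1] *= -1  # flip the rank-w difference so W- = w
    res = wilcoxon_signed_rank(x, d, method="asymptotic")
    assert res.w_statistic == w
    assert round(res.p_value, 3) == expected
    oracle = wilcoxon_asymptotic_closed_form(w, 7)
    assert res.p_value == pytest.approx(oracle, rel=1e-12)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    d=st.lists(
        st.integers(-9, 9).filter(lambda v: v != 0), min_size=1, max_size=12
    )
)
def test_exact_p_matches_full_enumeration(d):
    """Exact p equals brute-force 2^n sign enumeration, ties included."""
    d = np.array(d, dtype=float)
    x = np.zeros_like(d)
    res = wilcoxon_signed_rank(x, d, method="exact")
    w_oracle, p_oracle = wilcoxon_exact_enumeration(d)
    assert res.w_statistic == pytest.approx(w_oracle)
    assert res.p_value == pytest.approx(p_oracle, rel=1e-12)


def test_matches_scipy_without_ties():
    rng = np.random.default_rng(8)
    for n in (6, 7, 10, 15):
        x = rng.normal(size=n)
        y = x + rng.normal(0.3, 1.0, size=n)
        ours = wilcoxon_signed_rank(x, y, method="exact")
        ref = scipy.stats.wilcoxon(y, x, mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        ours_a = wilcoxon_signed_rank(x, y, method="asymptotic")
        ref_a = scipy.stats.wilcoxon(y, x, correction=False, mode="approx")
        assert ours_a.p_value == pytest.approx(ref_a.pvalue, rel=1e-10)


def test_antisymmetry_under_sample_swap():
    rng = np.random.default_rng(2)
    x = rng.normal(size=9)
    y = x + rng.normal(0.5, 1.0, size=9)
    a = wilcoxon_signed_rank(x, y, method="exact")
    b = wilcoxon_signed_rank(y, x, method="exact")
    assert a.w_statistic == b.w_statistic
    assert a.p_value == b.p_value


def test_pratt_zero_handling():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 4.0, 5.0, 7.0])  # one zero difference
    wil = wilcoxon_signed_rank(x, y, zero_method="wilcox")
    pratt = wilcoxon_signed_rank(x, y, zero_method="pratt")
    assert wil.n_used == pratt.n_used == 3
    assert pratt.w_statistic >= wil.w_statistic  # zeros occupy the low ranks


# --------------------------------------------------------------------------
# Grid and peak extraction
# --------------------------------------------------------------------------


def test_fe5030_grid_has_nine_samples_per_muscle():
    res = synthetic_result(Motion.FE5030, lambda tr, m: np.ones(len(tr)))
    df = extract_grid_forces(res)
    assert len(df) == 9 * len(MUSCLES)
    assert df["force"].unique() == pytest.approx([1.0])


def test_constant_force_grid_sample_is_that_constant():
    res = synthetic_result(Motion.RUD15, lambda tr, m: np.full(len(tr), 4.25))
    df = extract_grid_forces(res)
    assert df["force"].to_numpy() == pytest.approx(np.full(len(df), 4.25))


def test_circumduction_limbs_sampled_separately():
    """Forces constructed to differ between limbs are reported separately."""

    def limb_force(tr, m):
        dfe = np.gradient(tr.theta_fe, tr.dt)
        return np.where(dfe > 0, 2.0, 5.0)

    res = synthetic_result(Motion.CCD_CW, limb_force)
    df = extract_grid_forces(res, [GridPoint("FE", 0.0, "inc"), GridPoint("FE", 0.0, "dec")])
    fcr = df[df.muscle == "FCR"].set_index("limb")["force"]
    assert fcr["inc"] == pytest.approx(2.0, abs=0.2)
    assert fcr["dec"] == pytest.approx(5.0, abs=0.2)


def test_missing_grid_value_raises():
    res = synthetic_result(Motion.FE5030, lambda tr, m: np.ones(len(tr)))
    with pytest.raises(MissingSampleError):
        extract_grid_forces(res, [GridPoint("FE", 80.0)])


def test_peak_force_of_sinusoid():
    def f(tr, m):
        return 5.0 + 3.0 * np.sin(2 * np.pi * tr.times / tr.period)

    res = synthetic_result(Motion.FE5030, f)
    assert peak_force(res, "FCR") == pytest.approx(8.0, abs=1e-3)


def test_peak_force_averages_cycle_maxima():
    def f(tr, m):
        n = tr.cycle_boundaries[1]
        out = np.zeros(len(tr))
        # steady-state cycles 1 and 2 have maxima 7 and 9 (cycle slices
        # share their boundary sample, so step just after the boundary)
        out[n : 2 * n + 1] = 7.0
        out[2 * n + 1 :] = 9.0
        return out

    res = synthetic_result(Motion.FE5030, f, cycles=3)
    assert peak_force(res, "ECU") == pytest.approx(8.0)


# --------------------------------------------------------------------------
# Cohort comparison
# --------------------------------------------------------------------------


def _cohort_frames(effect, n=7):
    grid_rows, peak_rows = [], []
    rng = np.random.default_rng(1)
    for i in range(n):
        base = 10.0 + rng.uniform(0, 2)
        for condition, scale in (("intact", 1.0), ("apl_ablated", effect)):
            for muscle in MUSCLES:
                mscale = scale if muscle == "FCR" else 1.0
                peak_rows.append(
                    {
                        "motion": "FE5030", "specimen": f"s{i}", "condition": condition,
                        "muscle": muscle, "peak_force": base * mscale,
                    }
                )
                for v in (-10.0, 0.0, 10.0):
                    grid_rows.append(
                        {
                            "motion": "FE5030", "specimen": f"s{i}", "condition": condition,
                            "muscle": muscle, "axis": "FE", "grid_value": v, "limb": "",
                            "force": base * mscale,
                        }
                    )
    return pd.DataFrame(grid_rows), pd.DataFrame(peak_rows)


def test_identical_conditions_flagged_degenerate():
    grid, peaks = _cohort_frames(effect=1.0)
    comp = compare_conditions(grid, peaks)
    assert comp["degenerate"].all()
    assert (comp["mean_pct_change"].dropna() == 0).all()
    assert not comp["significant"].any()


def test_uniform_25_percent_increase():
    grid, peaks = _cohort_frames(effect=1.25)
    comp = compare_conditions(grid, peaks)
    fcr_peak = comp[(comp.muscle == "FCR") & (comp.kind == "peak")].iloc[0]
    assert fcr_peak["mean_pct_change"] == pytest.approx(25.0)
    assert fcr_peak["p_exact"] == pytest.approx(2 / 128)
    assert fcr_peak["significant"]
    # row count: muscles x (grid values + 1 peak row)
    assert len(comp) == len(MUSCLES) * (3 + 1)


def test_unpaired_specimen_raises():
    grid, peaks = _cohort_frames(effect=1.25)
    missing_one = grid[~((grid.specimen == "s0") & (grid.condition == "apl_ablated"))]
    with pytest.raises(PairingError):
        compare_conditions(missing_one, peaks)


def test_summary_table_mentions_every_muscle():
    grid, peaks = _cohort_frames(effect=1.25)
    text = summarize_peaks(compare_conditions(grid, peaks))
    for m in MUSCLES:
        assert m in text
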