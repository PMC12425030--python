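"""Sample assignment, differential stability, aggregation, spatial correlation."""

import itertools

import nibabel as nib
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mwfomics as m
from mwfomics.errors import (
    DegenerateInputError,
    InputError,
    InsufficientRegionsError,
    UndefinedStabilityError,
)
from mwfomics.spatial import (
    UNASSIGNED,
    aggregate_donors,
    assign_samples,
    differential_stability,
    regional_profiles,
    spatial_correlation,
)


def make_volume():
    """Two labeled boxes in a 10^3 grid, 2 mm voxels, corner at origin."""
    lab = np.zeros((10, 10, 10), dtype=np.int16)
    lab[1:3, 1:3, 1:3] = 1
    lab[6:8, 6:8, 6:8] = 2
    return nib.Nifti1Image(lab, np.diag([2.0, 2.0, 2.0, 1.0]))


def samples_at(points):
    return pd.DataFrame(
        {
            "donor_id": "D1",
            "sample_id": [f"s{i}" for i in range(len(points))],
            "mni_x": [p[0] for p in points],
            "mni_y": [p[1] for p in points],
            "mni_z": [p[2] for p in points],
        }
    )


def brute_force_assign(points, label_img, max_dist):
    """Oracle: exhaustive scan over labeled voxel centers."""
    lab = np.asanyarray(label_img.dataobj)
    aff = label_img.affine
    inv = np.linalg.inv(aff)
    out = []
    centers = [(tuple(ijk), aff[:3, :3] @ ijk + aff[:3, 3]) for ijk in np.argwhere(lab > 0)]
    for p in points:
        p = np.asarray(p, dtype=float)
        ijk = np.rint(inv[:3, :3] @ p + inv[:3, 3]).astype(int)
        if (ijk >= 0).all() and (ijk < lab.shape).all() and lab[tuple(ijk)] > 0:
            out.append(int(lab[tuple(ijk)]))
            continue
        best = None
        for vox, c in centers:
            d = float(np.linalg.norm(p - c))
            key = (d, int(lab[vox]), vox)
            if best is None or key < best:
                best = key
        out.append(int(lab[best[2]]) if best[0] <= max_dist else UNASSIGNED)
    return out


def test_in_voxel_center_assigned_to_its_region():
    vol = make_volume()
    res = assign_samples(samples_at([(2.0, 2.0, 2.0), (12.0, 14.0, 12.0)]), vol)
    assert list(res["region_id"]) == [1, 2]
    assert list(res["assign_dist_mm"]) == [0.0, 0.0]


def test_two_mm_rule_either_side_of_threshold():
    vol = make_volume()
    # nearest labeled center of region 1 along x is at x=4 (voxel 2 is background)
    near = (5.9, 2.0, 2.0)  # 1.9 mm from the center at x=4
    far = (6.6, 2.0, 2.0)  # 2.6 mm away
    res = assign_samples(samples_at([near, far]), vol, max_dist_mm=2.0)
    assert res.loc[0, "region_id"] == 1
    assert res.loc[0, "assign_dist_mm"] == pytest.approx(1.9)
    assert res.loc[1, "region_id"] == UNASSIGNED


def test_matches_brute_force_oracle_on_random_volume(rng):
    lab = np.zeros((20, 20, 20), dtype=np.int16)
    lab[2:5, 2:5, 2:5] = 1
    lab[10:13, 3:6, 4:7] = 2
    lab[5:8, 14:17, 11:14] = 3
    lab[15:18, 15:18, 15:18] = 4
    affine = np.diag([1.5, 1.5, 1.5, 1.0])
    affine[:3, 3] = [-10.0, -12.0, -8.0]
    vol = nib.Nifti1Image(lab, affine)
    pts = rng.uniform(-15, 25, size=(400, 3))
    res = assign_samples(samples_at(pts), vol, max_dist_mm=2.0)
    expect = brute_force_assign(pts, vol, 2.0)
    assert list(res["region_id"]) == expect
    # the oracle must exercise all three cases
    assert (res["in_voxel"]).any()
    assert ((~res["in_voxel"]) & (res["region_id"] != UNASSIGNED)).any()
    assert (res["region_id"] == UNASSIGNED).any()


def test_enlarging_radius_is_monotone(rng):
    vol = make_volume()
    pts = rng.uniform(-2, 20, size=(200, 3))
    r0 = assign_samples(samples_at(pts), vol, max_dist_mm=0.0)
    r2 = assign_samples(samples_at(pts), vol, max_dist_mm=2.0)
    r5 = assign_samples(samples_at(pts), vol, max_dist_mm=5.0)
    # radius 0 assigns exactly the in-voxel samples
    assert ((r0["region_id"] != UNASSIGNED) == r0["in_voxel"]).all()
    for small, big in [(r0, r2), (r2, r5)]:
        assigned = small["region_id"] != UNASSIGNED
        assert (big.loc[assigned, "region_id"] == small.loc[assigned, "region_id"]).all()


def test_non_finite_coordinate_names_sample():
    vol = make_volume()
    s = samples_at([(np.nan, 0.0, 0.0)])
    with pytest.raises(InputError, match="s0"):
        assign_samples(s, vol)


# --- profiles ------------------------------------------------------------


def profile_frame(rows):
    return pd.DataFrame(rows, columns=["probe_id", "donor_id", "region_id", "mean_expr"])


def test_profile_means_match_groupby_oracle(bundle):
    assigned = assign_samples(bundle.donor_samples, bundle.label_volume)
    probe = bundle.probes["probe_id"].iloc[0]
    prof = regional_profiles(assigned, probe)
    kept = assigned[assigned["region_id"] != UNASSIGNED]
    for _, row in prof.iterrows():
        sel = kept[(kept["donor_id"] == row["donor_id"]) & (kept["region_id"] == row["region_id"])]
        assert row["mean_expr"] == pytest.approx(sel[probe].mean(), abs=1e-12)


def test_single_sample_profiles_equal_raw_values():
    assigned = pd.DataFrame(
        {
            "donor_id": ["D1", "D1"],
            "sample_id": ["a", "b"],
            "region_id": [1, 2],
            "probe": [0.5, 0.9],
        }
    )
    prof = regional_profiles(assigned, "probe")
    assert list(prof["mean_expr"]) == [0.5, 0.9]


def test_unknown_probe_rejected(bundle):
    assigned = assign_samples(bundle.donor_samples, bundle.label_volume)
    with pytest.raises(InputError):
        regional_profiles(assigned, "nonexistent_probe")


# --- differential stability ---------------------------------------------


def spearman_oracle(a, b):
    """Midranks + Pearson on ranks."""
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    return np.corrcoef(ra, rb)[0, 1]


def test_identical_rankings_give_ds_one():
    rows = []
    for donor, scale in (("D1", 1.0), ("D2", 10.0)):
        for rid, v in enumerate([0.1, 0.5, 0.9, 0.3]):
            rows.append(("p1", donor, rid, scale * v))
    ds, selected = differential_stability(profile_frame(rows))
    assert ds["p1"] == pytest.approx(1.0)
    assert selected == "p1"


def test_ds_matches_rank_oracle(rng):
    donors = [f"D{i}" for i in range(4)]
    regions = list(range(8))
    rows = []
    values = {}
    for pid in ("pA", "pB"):
        for d in donors:
            vals = rng.normal(size=len(regions))
            values[(pid, d)] = vals
            rows += [(pid, d, r, v) for r, v in zip(regions, vals)]
    ds, _ = differential_stability(profile_frame(rows))
    for pid in ("pA", "pB"):
        expect = np.mean(
            [
                spearman_oracle(values[(pid, d1)], values[(pid, d2)])
                for d1, d2 in itertools.combinations(donors, 2)
            ]
        )
        assert ds[pid] == pytest.approx(expect, abs=1e-12)


def test_ds_invariant_under_monotone_transforms(rng):
    donors = ["D1", "D2", "D3"]
    vals = {d: rng.normal(size=6) for d in donors}
    base = profile_frame([("p", d, r, vals[d][r]) for d in donors for r in range(6)])
    exp = profile_frame([("p", d, r, np.exp(vals[d][r])) for d in donors for r in range(6)])
    aff = profile_frame([("p", d, r, 3.0 * vals[d][r] - 7.0) for d in donors for r in range(6)])
    ds0, _ = differential_stability(base)
    for other in (exp, aff):
        ds1, _ = differential_stability(other)
        assert ds1["p"] == pytest.approx(ds0["p"], abs=1e-12)


def test_fewer_than_two_donors_undefined():
    rows = [("p", "D1", r, float(r)) for r in range(5)]
    with pytest.raises(UndefinedStabilityError):
        differential_stability(profile_frame(rows))


def test_pair_with_few_common_regions_skipped_probe_never_selected():
    rows = []
    # pB: donors share only 2 regions -> no valid pair -> DS NaN
    for d, regions in (("D1", [0, 1]), ("D2", [1, 2])):
        rows += [("pB", d, r, float(r)) for r in regions]
    for d in ("D1", "D2"):
        rows += [("pA", d, r, float(r)) for r in range(4)]
    ds, selected = differential_stability(profile_frame(rows), probe_order=["pB", "pA"])
    assert np.isnan(ds["pB"]) and selected == "pA"


def test_planted_stable_probe_selected(bundle):
    from mwfomics.spatial import select_probe

    assigned = assign_samples(bundle.donor_samples, bundle.label_volume)
    ds, selected, _ = select_probe(assigned, bundle.probes)
    assert selected == bundle.truth.stable_probe["MBP"]
    unstable = [p for p in ds.index if p != selected]
    assert (ds[selected] > ds[unstable]).all()


# --- aggregation & correlation -------------------------------------------


def test_aggregate_single_donor_identity():
    prof = profile_frame([("p", "D1", 1, 0.4), ("p", "D1", 2, 0.8)])
    agg = aggregate_donors(prof)
    assert agg.to_dict() == {1: 0.4, 2: 0.8}


def test_aggregate_two_donors_exact_mean():
    prof = profile_frame([("p", "D1", 1, 0.4), ("p", "D2", 1, 0.8), ("p", "D1", 2, 0.2)])
    agg = aggregate_donors(prof)
    assert agg[1] == pytest.approx(0.6)
    assert agg[2] == pytest.approx(0.2)


def test_aggregate_matches_two_stage_mean_oracle(rng):
    rows = []
    for d in ("D1", "D2", "D3"):
        for r in rng.choice(10, size=6, replace=False):
            rows.append(("p", d, int(r), float(rng.normal())))
    prof = profile_frame(rows)
    agg = aggregate_donors(prof)
    for rid in agg.index:
        donor_means = prof[prof["region_id"] == rid].groupby("donor_id")["mean_expr"].mean()
        assert agg[rid] == pytest.approx(donor_means.mean(), abs=1e-12)


def test_collinear_regions_give_exact_fit():
    mrna = pd.Series({i: float(i) for i in range(5)})
    mwf = 2.0 * mrna + 1.0
    res = spatial_correlation(mwf, mrna)
    assert res.r == pytest.approx(1.0)
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(1.0)


def test_r_symmetric_slope_not(rng):
    a = pd.Series(rng.normal(size=10))
    b = pd.Series(0.5 * a + rng.normal(size=10))
    fwd = spatial_correlation(a, b)
    rev = spatial_correlation(b, a)
    assert fwd.r == pytest.approx(rev.r, abs=1e-12)
    assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)
    assert fwd.slope != pytest.approx(rev.slope)


def test_permuted_labels_center_r_at_zero(rng):
    mrna = pd.Series(rng.normal(size=12))
    mwf = pd.Series(0.9 * mrna + 0.1 * rng.normal(size=12))
    rs = []
    for _ in range(300):
        perm = pd.Series(mwf.to_numpy()[rng.permutation(12)], index=mwf.index)
        rs.append(spatial_correlation(perm, mrna).r)
    assert abs(np.mean(rs)) < 3.0 / np.sqrt(11 * 300)  # null mean ~ 0


def test_insufficient_or_degenerate_inputs_rejected():
    with pytest.raises(InsufficientRegionsError):
        spatial_correlation(pd.Series({1: 0.1, 2: 0.2}), pd.Series({1: 1.0, 2: 2.0}))
    flat = pd.Series({1: 0.5, 2: 0.5, 3: 0.5})
    varying = pd.Series({1: 1.0, 2: 2.0, 3: 3.0})
    with pytest.raises(DegenerateInputError):
        spatial_correlation(flat, varying)


def test_spearman_flag_gives_rank_correlation(rng):
    a = pd.Series(rng.normal(size=10))
    b = pd.Series(np.exp(a) + 0.01 * rng.normal(size=10))
    res = spatial_correlation(a, b, method="spearman")
    assert res.r == pytest.approx(1.0)


def test_low_noise_pipeline_recovers_strong_positive_r(bundle):
    from mwfomics.spatial import select_probe

    assigned = assign_samples(bundle.donor_samples, bundle.label_volume)
    ds, selected, prof = select_probe(assigned, bundle.probes)
    mrna = aggregate_donors(prof[prof["probe_id"] == selected])
    mwf = m.regional_mean_mwf(bundle.cohort)
    res = spatial_correlation(mwf, mrna, region_table=bundle.truth.region_table)
    assert res.r > 0.9
    assert set(res.per_region["tissue_class"]) == {"white_matter", "deep_gray"}
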