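"""End-to-end studies: tumor recurrence analysis and liver device-dependence.

``run_tumor_study`` reproduces the analysis structure of the clinical study
on a cohort table (real or synthetic): per-group univariate screening of the
11 features, the subset-size stability experiment, per-group AIC-selected
4-feature signatures and both train/validation directions with DeLong
comparison against SUVmax.

``run_liver_study`` reproduces the reference-region reproducibility study:
identical homogeneous liver truths imaged through the two device profiles,
features compared between groups with Wilcoxon tests under four grid
conditions — native, resampled to the G1 grid, to the G2 grid and to a
2 mm isotropic grid (bicubic interpolation). MV and TLG are omitted there:
the reference VOI has a fixed prescribed volume, which makes them
group-constant by construction.

Every number in a report is reproducible from (config, seed); reports are
CSV tables plus a JSON run manifest (config echo, seeds, package version).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import FEATURE_NAMES, extract_all
from .signature import cross_group_validation
from .stats import subset_stability, univariate_table, wilcoxon_test
from .synthetic import (
    G1_PROFILE,
    G2_PROFILE,
    CohortSpec,
    simulate_cohort,
    simulate_liver,
)
from .segmentation import sphere_voi
from .volumes import resample_grid

__all__ = ["run_tumor_study", "run_liver_study", "LIVER_FEATURES"]

#: Features reported in the liver comparison (fixed-volume VOI: MV and TLG
#: are constant within each group and carry no device information).
LIVER_FEATURES = (
    "SUVmean",
    "SUVmax",
    "SUVpeak",
    "Homogeneity",
    "Entropy",
    "SRE",
    "LRE",
    "LGZE",
    "HGZE",
)

#: Grid conditions of the liver comparison.
LIVER_CONDITIONS = ("native", "G1_grid", "G2_grid", "iso2mm")


def _manifest(config: dict, seed, out_dir: Path | None) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str)
    man = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    if out_dir is not None:
        (out_dir / "manifest.json").write_text(json.dumps(man, indent=2, default=str))
    return man


def run_tumor_study(
    cohort: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    spec: CohortSpec | None = None,
    subset_size: int | None = None,
    n_draws: int = 100,
    n_boot: int = 2000,
    k: int = 4,
    method: str = "exhaustive",
    seed: int = 0,
) -> dict:
    """Run the full recurrence analysis on a cohort table.

    ``cohort`` needs columns patient_id, group, outcome and the 11 features;
    when None a synthetic cohort is generated from ``spec`` (default spec if
    None) and features are extracted from the simulated scanner images.
    Returns a report dict with the univariate tables, subset-stability
    means, and the two cross-group validation results; writes CSV/JSON files
    when ``out_dir`` is given.
    """
    config = {
        "subset_size": subset_size,
        "n_draws": n_draws,
        "n_boot": n_boot,
        "k": k,
        "method": method,
        "seed": seed,
        "synthetic": cohort is None,
    }
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        spec = spec or CohortSpec(seed=seed)
        _, cohort = simulate_cohort(spec, extract=True)
    groups = sorted(cohort["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 scanner groups, found {groups}")
    g_a, g_b = groups
    report: dict = {"cohort_size": {g: int((cohort["group"] == g).sum()) for g in groups}}

    rng = np.random.default_rng(seed)
    univariate = {}
    for g in groups:
        tab = univariate_table(cohort, g, n_boot=n_boot, seed=rng)
        univariate[g] = tab
        if out_path is not None:
            tab.to_csv(out_path / f"univariate_{g}.csv")
    report["univariate"] = univariate

    sizes = report["cohort_size"]
    larger = max(groups, key=lambda g: sizes[g])
    smaller = min(groups, key=lambda g: sizes[g])
    ssize = subset_size or sizes[smaller]
    if ssize <= sizes[larger]:
        stab = subset_stability(cohort, larger, ssize, n_draws=n_draws, seed=seed)
        report["subset_stability"] = {"group": larger, "subset_size": ssize, "mean_p": stab}
        if out_path is not None:
            stab.to_csv(out_path / f"subset_stability_{larger}.csv")

    validations = {}
    for train, test in ((g_a, g_b), (g_b, g_a)):
        res = cross_group_validation(
            cohort, train, test, k=k, method=method, n_boot=n_boot, seed=seed
        )
        validations[f"{train}->{test}"] = res
        if out_path is not None:
            res.model.save(out_path / f"signature_{train}.json")
            (out_path / f"validation_{train}_to_{test}.json").write_text(
                json.dumps(res.to_dict(), indent=2)
            )
    report["validation"] = validations
    report["manifest"] = _manifest(config, seed, out_path)
    if out_path is not None:
        cohort.to_csv(out_path / "cohort.csv", index=False)
    return report


def _liver_features_under_conditions(image, voi_native, sphere_volume_mL):
    """Feature sets of one liver image under the four grid conditions."""
    rows = {}
    rows["native"] = extract_all(image, voi_native, names=LIVER_FEATURES)
    for cond, spacing in (
        ("G1_grid", G1_PROFILE.voxel_size),
        ("G2_grid", G2_PROFILE.voxel_size),
        ("iso2mm", (2.0, 2.0, 2.0)),
    ):
        res = resample_grid(image, spacing)
        center = tuple(
            o + (n - 1) / 2.0 * s
            for o, n, s in zip(res.origin, res.shape, res.spacing)
        )
        voi = sphere_voi(res, center, sphere_volume_mL)
        rows[cond] = extract_all(res, voi, names=LIVER_FEATURES)
    return rows


def run_liver_study(
    n_per_group: int = 40,
    out_dir: str | Path | None = None,
    profiles: dict | None = None,
    sphere_volume_mL: float = 75.5,
    seed: int = 0,
) -> dict:
    """Cross-device liver reproducibility study on synthetic phantoms.

    Images ``n_per_group`` identical homogeneous liver truths through each
    device profile (independent noise realisations), extracts the 9 liver
    features under the four grid conditions, and reports per-condition
    Wilcoxon p-values between the groups plus the underlying feature tables.
    """
    profiles = profiles or {"G1": G1_PROFILE, "G2": G2_PROFILE}
    if len(profiles) != 2:
        raise ValueError("exactly two device profiles are required")
    config = {
        "n_per_group": n_per_group,
        "sphere_volume_mL": sphere_volume_mL,
        "seed": seed,
        "profiles": {k: vars(v) for k, v in profiles.items()},
    }
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    rows = []
    for group, profile in sorted(profiles.items()):
        for i in range(n_per_group):
            s = int(master.integers(0, 2**31 - 1))
            image, voi = simulate_liver(profile, sphere_volume_mL, seed=s)
            for cond, feats in _liver_features_under_conditions(
                image, voi, sphere_volume_mL
            ).items():
                rows.append({"group": group, "replicate": i, "condition": cond, **feats})
    table = pd.DataFrame(rows)

    g_a, g_b = sorted(profiles)
    pvals = pd.DataFrame(index=list(LIVER_FEATURES), columns=list(LIVER_CONDITIONS), dtype=float)
    for cond in LIVER_CONDITIONS:
        sub = table[table["condition"] == cond]
        for feat in LIVER_FEATURES:
            x = sub.loc[sub["group"] == g_a, feat].to_numpy()
            y = sub.loc[sub["group"] == g_b, feat].to_numpy()
            pvals.loc[feat, cond] = wilcoxon_test(x, y)
    if out_path is not None:
        table.to_csv(out_path / "liver_features.csv", index=False)
        pvals.to_csv(out_path / "liver_pvalues.csv")
    report = {"features": table, "p_values": pvals}
    report["manifest"] = _manifest(config, seed, out_path)
    return report
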