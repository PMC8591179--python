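"""End-to-end orchestration of the synthetic guidance study.

``run_study`` executes the full chain — phantom generation, segmentation,
fiducial registration with the 1 mm FRE gate, simulated osteotomies under
the four guidance conditions, margin scoring, gaze/workload metrics, and
the statistical comparison — deterministically from a single master seed.
``reproduce_table1`` recomputes the published intratumoral-cut analysis
(percentages, continuity-corrected odds ratios, exact test) from the
packaged count fixture.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import (
    behavior,
    margins,
    meshdist,
    phantom,
    registration,
    segmentation,
    stats,
    workload,
)
from .behavior import ConditionNoise, GuidanceCondition

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "reproduce_table1",
    "derive_seed",
    "DEFAULT_INTRATUMORAL_RATES",
    "DEFAULT_GAZE_FRACTIONS",
]

CONDITIONS = tuple(GuidanceCondition)

# Observed per-condition study parameters driving the generators:
# intratumoral cut rates and screen-gaze fractions for
# unguided / AR / IN / AR+IN, and mean task durations in seconds.
DEFAULT_INTRATUMORAL_RATES = {
    GuidanceCondition.UNGUIDED: 0.207,
    GuidanceCondition.AR: 0.094,
    GuidanceCondition.IN: 0.012,
    GuidanceCondition.AR_IN: 0.0,
}
DEFAULT_GAZE_FRACTIONS = {
    GuidanceCondition.UNGUIDED: 0.555,
    GuidanceCondition.AR: 0.0,
    GuidanceCondition.IN: 0.785,
    GuidanceCondition.AR_IN: 0.618,
}
DEFAULT_DURATION_MEANS = {
    GuidanceCondition.UNGUIDED: 215.0,
    GuidanceCondition.AR: 117.0,
    GuidanceCondition.IN: 134.0,
    GuidanceCondition.AR_IN: 120.0,
}
# Six-subscale TLX means (mental, physical, temporal, performance, effort,
# frustration): unguided and AR high on mental demand / effort /
# frustration, the combined condition lowest.  Invented magnitudes; only
# the ordering is informed by the study's qualitative findings.
DEFAULT_TLX_MEANS = {
    GuidanceCondition.UNGUIDED: (70.0, 40.0, 50.0, 55.0, 70.0, 65.0),
    GuidanceCondition.AR: (68.0, 40.0, 45.0, 52.0, 68.0, 62.0),
    GuidanceCondition.IN: (52.0, 38.0, 45.0, 42.0, 55.0, 45.0),
    GuidanceCondition.AR_IN: (40.0, 35.0, 40.0, 35.0, 45.0, 35.0),
}

# Four tumor models: unions of overlapping ellipsoids with distinct shapes,
# standing in for the four physical moldable-material masses.
_TUMOR_MODEL_GEOMETRIES = (
    (
        phantom.Ellipsoid((0.0, 8.0, 0.0), (14.0, 11.0, 12.0)),
        phantom.Ellipsoid((6.0, -2.0, 4.0), (9.0, 12.0, 8.0)),
    ),
    (
        phantom.Ellipsoid((-4.0, 0.0, 2.0), (12.0, 14.0, 10.0)),
        phantom.Ellipsoid((5.0, 5.0, -3.0), (10.0, 9.0, 11.0)),
    ),
    (
        phantom.Ellipsoid((0.0, 0.0, 0.0), (16.0, 12.0, 11.0)),
    ),
    (
        phantom.Ellipsoid((2.0, -5.0, 0.0), (11.0, 13.0, 12.0)),
        phantom.Ellipsoid((-5.0, 4.0, 3.0), (9.0, 10.0, 9.0)),
        phantom.Ellipsoid((0.0, 0.0, -6.0), (10.0, 10.0, 7.0)),
    ),
)


def derive_seed(master: int, *tags) -> int:
    """Stable sub-seed from the master seed and a tuple of stage/id tags.

    Strings are hashed with CRC32 so the hierarchy is reproducible across
    processes; the result stays below 2**31.  Adding new stages or cuts
    never perturbs the seeds of existing ones.
    """
    ints = [int(master) & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, str):
            ints.append(zlib.crc32(tag.encode()) & 0x7FFFFFFF)
        else:
            ints.append(int(tag) & 0x7FFFFFFF)
    return int(np.random.SeedSequence(ints).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class StudyConfig:
    """All knobs of one synthetic study run."""

    seed: int = 0
    n_tumor_models: int = 4
    n_surgeons: int = 5
    margin_target_mm: float = 10.0
    grid_step_mm: float = 0.5
    # Phantom scale; the study default is CBCT-like 0.5 mm over 256^3.
    volume_shape: tuple[int, int, int] = (256, 256, 256)
    voxel_spacing_mm: float = 0.5
    noise_sd: float = 30.0
    bone_level: float = 700.0
    tumor_level: float = 1200.0
    threshold: float | None = None  # default: midpoint of bone/tumor levels
    fiducial_noise_sd_mm: float = 0.15
    fre_limit_mm: float = 1.0
    max_registration_attempts: int = 10
    intratumoral_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_INTRATUMORAL_RATES)
    )
    gaze_fractions: dict = field(default_factory=lambda: dict(DEFAULT_GAZE_FRACTIONS))
    gaze_mean_dwell_s: float = 5.0
    tlx_means: dict = field(default_factory=lambda: dict(DEFAULT_TLX_MEANS))
    tlx_sd: float = 12.0
    duration_means: dict = field(default_factory=lambda: dict(DEFAULT_DURATION_MEANS))
    duration_sd: float = 30.0
    drop_probability: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_tumor_models <= 4:
            raise ValueError("1-4 tumor models supported")
        if not 1 <= self.n_surgeons <= 5:
            raise ValueError("1-5 surgeons supported")
        if not 0 <= self.drop_probability < 1:
            raise ValueError("drop probability must lie in [0, 1)")
        self.intratumoral_rates = {
            GuidanceCondition(k): float(v) for k, v in self.intratumoral_rates.items()
        }
        self.gaze_fractions = {
            GuidanceCondition(k): float(v) for k, v in self.gaze_fractions.items()
        }
        self.tlx_means = {
            GuidanceCondition(k): tuple(v) for k, v in self.tlx_means.items()
        }
        self.duration_means = {
            GuidanceCondition(k): float(v) for k, v in self.duration_means.items()
        }

    def condition_noise(self) -> dict[GuidanceCondition, ConditionNoise]:
        return {
            cond: behavior.calibrate_condition_noise(rate, self.margin_target_mm)
            for cond, rate in self.intratumoral_rates.items()
        }

    def phantom_spec(self, tumor_model: int) -> phantom.PhantomSpec:
        shape = tuple(self.volume_shape)
        spacing = (self.voxel_spacing_mm,) * 3
        extent = np.array(shape) * self.voxel_spacing_mm
        origin = tuple(-extent / 2)
        return phantom.PhantomSpec(
            shape=shape,
            spacing=spacing,
            origin=origin,
            tumors=(phantom.TumorSpec(_TUMOR_MODEL_GEOMETRIES[tumor_model - 1]),),
            bone_level=self.bone_level,
            tumor_level=self.tumor_level,
            noise_sd=self.noise_sd,
            seed=derive_seed(self.seed, "phantom", tumor_model),
        )

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        for key in ("intratumoral_rates", "gaze_fractions", "tlx_means", "duration_means"):
            raw[key] = {cond.value: val for cond, val in raw[key].items()}
        raw["volume_shape"] = list(raw["volume_shape"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("config must state the master seed")
        if "volume_shape" in raw:
            raw["volume_shape"] = tuple(raw["volume_shape"])
        return cls(**raw)

    def digest(self) -> str:
        raw = asdict(self)
        for key in ("intratumoral_rates", "gaze_fractions", "tlx_means", "duration_means"):
            raw[key] = {cond.value: val for cond, val in raw[key].items()}
        return hashlib.sha256(
            json.dumps(raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyReport:
    """Everything one study run produced, ready to serialize."""

    per_cut: pd.DataFrame
    contingency: stats.ContingencyTable
    fisher_p: float
    or_table: pd.DataFrame
    logistic: stats.LogisticFit | None
    gaze: pd.DataFrame
    gaze_sessions: pd.DataFrame
    tlx: pd.DataFrame
    kw_results: dict
    registration_log: pd.DataFrame
    provenance: dict

    def intratumoral_rates(self) -> pd.Series:
        counts = self.contingency.counts
        return pd.Series(
            100.0 * counts[0] / counts.sum(axis=0),
            index=list(self.contingency.col_labels),
        )

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_cut.to_csv(outdir / "per_cut.csv", index=False)
        self.or_table.to_csv(outdir / "odds_ratios.csv", index=False)
        self.gaze.to_csv(outdir / "gaze_by_condition.csv", index=False)
        self.gaze_sessions.to_csv(outdir / "gaze_sessions.csv", index=False)
        self.tlx.to_csv(outdir / "tlx.csv", index=False)
        self.registration_log.to_csv(outdir / "registration_log.csv", index=False)
        summary = {
            "contingency": {
                "conditions": list(self.contingency.col_labels),
                "intratumoral": self.contingency.counts[0].tolist(),
                "clear": self.contingency.counts[1].tolist(),
            },
            "fisher_p": self.fisher_p,
            "intratumoral_pct": self.intratumoral_rates().round(6).to_dict(),
            "kruskal_wallis": self.kw_results,
            "provenance": self.provenance,
        }
        if self.logistic is not None:
            summary["logistic"] = {
                "method": self.logistic.method,
                "odds_ratios": {
                    k: float(v) for k, v in self.logistic.odds_ratios()["or"].items()
                },
            }
        with open(outdir / "report.json", "w") as fh:
            json.dump(summary, fh, indent=2)


def _score_cut_with_fallback(
    cut: behavior.CutRecord,
    sdf: segmentation.SignedDistanceField,
    mesh: trimesh.Trimesh,
    step: float,
) -> margins.MarginSummary:
    """Score via the voxel field; fall back to exact mesh distance when the
    plane region (a far-outlying unguided cut) exits the field volume."""
    region = margins.plane_region_from_cut(cut, step)
    try:
        dmap = margins.sample_distances(region, sdf)
    except ValueError:
        grid = region.grid_points()
        d = meshdist.signed_point_mesh_distance(mesh, grid.reshape(-1, 3))
        dmap = margins.DistanceMap(d.reshape(grid.shape[:2]), step)
    return margins.summarize(dmap)


def _register_with_gate(
    fiducials: phantom.FiducialSet, config: StudyConfig, tumor_model: int
) -> dict:
    """Simulate tracked fiducial digitization and apply the FRE gate.

    Measurement noise is redrawn (a fresh digitization attempt) until the
    FRE passes the gate, up to the configured number of attempts.
    """
    for attempt in range(1, config.max_registration_attempts + 1):
        rng = np.random.default_rng(
            derive_seed(config.seed, "registration", tumor_model, attempt)
        )
        measured = fiducials.positions_world + rng.normal(
            0.0, config.fiducial_noise_sd_mm, size=fiducials.positions_world.shape
        )
        transform, fre = registration.fit_rigid(
            fiducials.positions_image, measured, "image", "tracker"
        )
        if registration.gate_registration(fre, config.fre_limit_mm):
            return {
                "tumor_id": tumor_model,
                "attempt": attempt,
                "fre_mm": fre,
                "accepted": True,
                "transform": transform,
            }
    return {
        "tumor_id": tumor_model,
        "attempt": config.max_registration_attempts,
        "fre_mm": fre,
        "accepted": False,
        "transform": transform,
    }


def run_study(config: StudyConfig, progress: bool = False) -> StudyReport:
    """Execute the full factorial study: tumors x sites x surgeons x conditions."""
    noise_table = config.condition_noise()
    threshold = (
        config.threshold
        if config.threshold is not None
        else 0.5 * (config.bone_level + config.tumor_level)
    )

    scored: list[tuple[behavior.CutRecord, margins.MarginSummary]] = []
    registration_rows = []
    gaze_streams: dict = {}
    tlx_responses: dict = {}

    for tumor_model in range(1, config.n_tumor_models + 1):
        spec = config.phantom_spec(tumor_model)
        volume, _, fiducials, sites, _ = phantom.generate_phantom(spec)
        label = segmentation.segment_tumor(volume, threshold)
        sdf = segmentation.signed_distance(label)
        mesh = segmentation.extract_surface(label)

        reg = _register_with_gate(fiducials, config, tumor_model)
        registration_rows.append(
            {k: reg[k] for k in ("tumor_id", "attempt", "fre_mm", "accepted")}
        )
        if not reg["accepted"]:
            raise RuntimeError(
                f"registration stage failed for tumor model {tumor_model}: "
                f"FRE {reg['fre_mm']:.3f} mm above the {config.fre_limit_mm} mm gate "
                f"after {config.max_registration_attempts} attempts"
            )

        ideal_origins = {
            site.site_id: behavior.plan_ideal_plane(site, sdf, config.margin_target_mm)
            for site in sites
        }
        for surgeon in range(1, config.n_surgeons + 1):
            for cond_idx, condition in enumerate(CONDITIONS):
                session_seed = derive_seed(
                    config.seed, "session", tumor_model, surgeon, cond_idx
                )
                duration = behavior.generate_duration(
                    config.duration_means[condition], config.duration_sd, session_seed
                )
                gaze_streams[(condition.value, (tumor_model, surgeon))] = (
                    behavior.generate_gaze_stream(
                        duration,
                        config.gaze_fractions[condition],
                        config.gaze_mean_dwell_s,
                        derive_seed(config.seed, "gaze", tumor_model, surgeon, cond_idx),
                    )
                )
                tlx_responses[(condition.value, (tumor_model, surgeon))] = (
                    behavior.generate_tlx(
                        config.tlx_means[condition],
                        config.tlx_sd,
                        derive_seed(config.seed, "tlx", tumor_model, surgeon, cond_idx),
                    )
                )
                for site in sites:
                    cut_seed = derive_seed(
                        config.seed, "cut", tumor_model, surgeon, cond_idx, site.site_id
                    )
                    if config.drop_probability > 0:
                        drop_rng = np.random.default_rng(
                            derive_seed(
                                config.seed,
                                "drop",
                                tumor_model,
                                surgeon,
                                cond_idx,
                                site.site_id,
                            )
                        )
                        if drop_rng.random() < config.drop_probability:
                            continue
                    cut = behavior.simulate_cut(
                        site,
                        sdf,
                        config.margin_target_mm,
                        noise_table[condition],
                        cut_seed,
                        condition=condition,
                        surgeon_id=surgeon,
                        tumor_id=tumor_model,
                        ideal_origin=ideal_origins[site.site_id],
                    ).with_duration(duration / len(sites))
                    summary = _score_cut_with_fallback(
                        cut, sdf, mesh, config.grid_step_mm
                    )
                    scored.append((cut, summary))
        if progress:
            print(f"tumor model {tumor_model}: {len(scored)} cuts scored")

    per_cut = margins.summaries_to_frame(scored)

    cond_labels = [c.value for c in CONDITIONS]
    yes = [
        int(per_cut.query("condition == @c")["intratumoral"].sum()) for c in cond_labels
    ]
    totals = [int((per_cut["condition"] == c).sum()) for c in cond_labels]
    contingency = stats.ContingencyTable(
        np.array([yes, [t - y for t, y in zip(totals, yes)]]),
        ("intratumoral", "clear"),
        tuple(cond_labels),
    )
    if (contingency.counts.sum(axis=1) == 0).any():
        fisher_p = 1.0  # degenerate outcome row: only one table has these margins
    else:
        fisher_p = stats.fisher_exact(contingency)

    or_rows = []
    ref = GuidanceCondition.AR.value
    ref_idx = cond_labels.index(ref)
    for i, cond in enumerate(cond_labels):
        if cond == ref:
            continue
        res = stats.odds_ratio_cc(
            (yes[i], totals[i] - yes[i]),
            (yes[ref_idx], totals[ref_idx] - yes[ref_idx]),
            reference_name=ref,
        )
        or_rows.append(
            {
                "condition": cond,
                "reference": ref,
                "odds_ratio": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    or_table = pd.DataFrame(or_rows)

    logistic = None
    if 0 < per_cut["intratumoral"].sum() < len(per_cut):
        try:
            logistic = stats.logistic_fit(
                per_cut["intratumoral"].astype(int).to_numpy(),
                per_cut[["condition", "tumor_id", "surgeon_id"]].astype(str),
                reference_levels={"condition": ref},
            )
        except (RuntimeError, ValueError):
            logistic = None  # sparse small runs may defeat even the penalized fit

    gaze_by_condition = workload.gaze_table(gaze_streams)
    gaze_sessions = workload.gaze_table(gaze_streams, by_condition=False)
    tlx = workload.tlx_table(tlx_responses)

    gaze_groups = [
        gaze_sessions.query("condition == @c")["pct_screen"].to_numpy()
        for c in cond_labels
    ]
    tlx_groups = [
        tlx.query("condition == @c")["overall"].to_numpy() for c in cond_labels
    ]
    dur_groups = [
        per_cut.query("condition == @c")["duration_s"].to_numpy() for c in cond_labels
    ]
    kw_results = {}
    for name, groups in (
        ("gaze_pct_screen", gaze_groups),
        ("tlx_overall", tlx_groups),
        ("duration_s", dur_groups),
    ):
        h, p = stats.kruskal_wallis(groups)
        kw_results[name] = {
            "H": h,
            "p": p,
            "posthoc": stats.sdcf_posthoc(groups, cond_labels).to_dict("records"),
        }

    provenance = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_cuts": int(len(per_cut)),
        "package": "osteomargin",
    }
    return StudyReport(
        per_cut=per_cut,
        contingency=contingency,
        fisher_p=fisher_p,
        or_table=or_table,
        logistic=logistic,
        gaze=gaze_by_condition,
        gaze_sessions=gaze_sessions,
        tlx=tlx,
        kw_results=kw_results,
        registration_log=pd.DataFrame(registration_rows),
        provenance=provenance,
    )


def sphere_study_field(
    radius_mm: float = 25.0,
    spacing_mm: float = 0.5,
    margin_target_mm: float = 10.0,
    max_offset_mm: float = 75.0,
) -> tuple[segmentation.SignedDistanceField, phantom.OsteotomySite]:
    """Digitized-sphere tumor field sized for the calibration round trip.

    The sphere sits at the origin; the returned site's nominal plane is
    normal to +z, so offset noise slides the cut plane along z.  The
    volume covers plane offsets up to ``max_offset_mm`` beyond the ideal
    plane so even extreme noise draws stay inside the field.  The sphere
    radius is large relative to the margin so that a plane overshooting
    *through* the whole tumor (which the closed-form intratumoral
    probability Phi(-m/sigma) neglects) has negligible probability.
    """
    z_ideal = radius_mm + margin_target_mm
    lateral = max(radius_mm + 5.0, margins.HALF_LENGTH_MM + 5.0)
    x = np.arange(-lateral, lateral + spacing_mm / 2, spacing_mm)
    z = np.arange(
        -(radius_mm + 5.0), z_ideal + max_offset_mm + spacing_mm / 2, spacing_mm
    )
    mask = (
        (x**2)[:, None, None] + (x**2)[None, :, None] + (z**2)[None, None, :]
    ) <= radius_mm**2
    label = phantom.Volume3D(
        mask.astype(np.int16), (spacing_mm,) * 3, (x[0], x[0], z[0])
    )
    sdf = segmentation.signed_distance(label)
    site = phantom.OsteotomySite(
        "Pa", np.array([0.0, 0.0, z_ideal]), np.array([0.0, 0.0, 1.0]),
        np.array([1.0, 0.0, 0.0]),
    )
    return sdf, site


def calibration_round_trip(
    n_cuts_per_condition: int = 5000,
    seed: int = 0,
    margin_target_mm: float = 10.0,
    rates: dict | None = None,
    grid_step_mm: float = 0.5,
) -> pd.DataFrame:
    """Simulate sphere-geometry cuts at the calibrated noise per condition.

    Returns a frame with the target and empirical intratumoral rates and
    binomial standard errors — the self-consistency check that the
    condition-noise calibration reproduces the observed study rates.
    """
    rates = rates or dict(DEFAULT_INTRATUMORAL_RATES)
    sdf, site = sphere_study_field(margin_target_mm=margin_target_mm)
    ideal = behavior.plan_ideal_plane(
        site, sdf, margin_target_mm, search_range=(-30.0, 20.0)
    )
    rows = []
    for cond_idx, (condition, rate) in enumerate(rates.items()):
        noise = behavior.calibrate_condition_noise(rate, margin_target_mm)
        hits = 0
        for i in range(n_cuts_per_condition):
            cut = behavior.simulate_cut(
                site,
                sdf,
                margin_target_mm,
                noise,
                derive_seed(seed, "calibration", cond_idx, i),
                condition=GuidanceCondition(condition),
                ideal_origin=ideal,
            )
            region = margins.plane_region_from_cut(cut, grid_step_mm)
            dmin = float(
                segmentation.query_distance(
                    sdf, region.grid_points().reshape(-1, 3)
                ).min()
            )
            hits += dmin <= 0
        empirical = hits / n_cuts_per_condition
        se = float(np.sqrt(max(rate * (1 - rate), 1e-12) / n_cuts_per_condition))
        rows.append(
            {
                "condition": GuidanceCondition(condition).value,
                "target_rate": rate,
                "empirical_rate": empirical,
                "n_cuts": n_cuts_per_condition,
                "binomial_se": se,
                "offset_sd_mm": noise.offset_sd,
            }
        )
    return pd.DataFrame(rows)


_EXPECTED_CONDITIONS = ("Unguided", "AR", "IN", "AR+IN")


def packaged_table1_path():
    return resources.files("osteomargin.data").joinpath("table1_counts.csv")


def reproduce_table1(fixture_path=None) -> dict:
    """Recompute the intratumoral-cut analysis from the packaged counts.

    Returns percentages per condition, the study total, Haldane-Anscombe
    odds ratios against the AR reference, and the 2 x 4 exact p-value.
    """
    if fixture_path is None:
        with resources.as_file(packaged_table1_path()) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(fixture_path)
    required = {"condition", "intratumoral", "clear"}
    if set(df.columns) != required:
        raise ValueError(f"fixture must have columns {sorted(required)}, got {list(df.columns)}")
    if tuple(df["condition"]) != _EXPECTED_CONDITIONS:
        raise ValueError(
            f"fixture conditions must be {_EXPECTED_CONDITIONS} in order, "
            f"got {tuple(df['condition'])}"
        )
    yes = df["intratumoral"].to_numpy(int)
    no = df["clear"].to_numpy(int)
    table = stats.ContingencyTable(
        np.array([yes, no]), ("intratumoral", "clear"), _EXPECTED_CONDITIONS
    )
    percentages = {
        cond: round(100.0 * y / (y + n), 1)
        for cond, y, n in zip(_EXPECTED_CONDITIONS, yes, no)
    }
    ref_idx = _EXPECTED_CONDITIONS.index("AR")
    odds_ratios = {}
    for i, cond in enumerate(_EXPECTED_CONDITIONS):
        if i == ref_idx:
            odds_ratios[cond] = None
            continue
        res = stats.odds_ratio_cc(
            (int(yes[i]), int(no[i])),
            (int(yes[ref_idx]), int(no[ref_idx])),
            reference_name="AR",
        )
        odds_ratios[cond] = {
            "or": round(res.estimate, 2),
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
        }
    return {
        "counts": df,
        "total": int(yes.sum() + no.sum()),
        "percentages": percentages,
        "odds_ratios": odds_ratios,
        "fisher_p": stats.fisher_exact(table),
    }
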