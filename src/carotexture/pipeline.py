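"""End-to-end orchestration over a cohort manifest.

The manifest is a CSV with one row per (mouse, week, side)::

    mouse_id,sex,week,side,image,annot,histology,cca,bulb,ica,eca

``image`` is an 8-bit TIFF/PNG frame, ``annot`` the frame annotation
JSON (reference regions + wall traces), ``histology`` the elastin line
annotation JSON; the last four columns are 0/1 plaque-presence flags.
Relative paths are resolved against the manifest's directory.

:func:`run_pipeline` runs normalize -> texture, elastin and plaque
scoring per record, joins everything into a tidy cohort table, runs the
cohort statistics, and writes schema-stable CSV outputs plus a JSON run
log carrying the config hash.  Re-running with identical inputs and
config produces bit-identical files; per-record failures are logged,
skipped and reported in the run summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import elastin as elastin_mod
from . import io as cio
from . import normalize as norm
from . import plaque as plaque_mod
from . import stats as stats_mod
from . import synth
from .errors import CarotextureError
from .texture import TextureParams, extract_feature_set

__all__ = [
    "PipelineConfig",
    "RunResult",
    "run_pipeline",
    "write_synthetic_study",
]

FEATURE_COLUMNS = ("gsm", "entropy", "gldm_con", "sgld_asm", "sgld_hom")
ELASTIN_COLUMNS = (
    "imt_um", "n_fibers_weighted", "dist_min_um", "dist_max_um",
    "dist_mean_um", "dist_median_um", "dist_sd_um",
)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, one section per stage."""

    adventitia_method: str = "iqr-band"
    target_density: float = norm.STANDARD_DENSITY
    roi_length_mm: float = 1.0
    texture: TextureParams = field(default_factory=TextureParams)
    contrast_week_pairs: tuple[tuple[int, int], ...] = ((6, 16), (6, 24))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        tex = TextureParams(**{k: tuple(v) if k == "angles" else v
                               for k, v in (raw.pop("texture", {}) or {}).items()})
        pairs = raw.pop("contrast_week_pairs", None)
        kwargs = dict(raw, texture=tex)
        if pairs is not None:
            kwargs["contrast_week_pairs"] = tuple(tuple(p) for p in pairs)
        return cls(**kwargs)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """Summary of one pipeline run."""

    out_dir: Path
    n_records: int
    n_processed: int
    skipped: list[dict]
    outputs: dict[str, Path]

    @property
    def ok(self) -> bool:
        return not self.skipped


def _resolve(base: Path, value: str) -> Path:
    p = Path(value)
    return p if p.is_absolute() else base / p


def _process_record(row: pd.Series, base: Path, config: PipelineConfig) -> dict:
    pixels = cio.read_image(_resolve(base, row["image"]))
    annot = cio.read_image_annotation(_resolve(base, row["annot"]))
    density = float(annot["pixel_density_per_mm"])

    # resample to the standard density first, then normalize
    scale = config.target_density / density
    pixels, density = norm.resample_to_density(pixels, density, config.target_density)
    if abs(scale - 1.0) > 1e-12:
        for key in ("blood", "adventitia", "im_upper", "im_lower"):
            annot[key] = annot[key] * scale

    blood_mask = cio.polygon_mask(annot["blood"], pixels.shape)
    adv_mask = cio.polygon_mask(annot["adventitia"], pixels.shape)
    blood_ref, adv_ref = norm.compute_reference_levels(
        pixels, blood_mask, adv_mask, adventitia_method=config.adventitia_method
    )
    image = norm.normalize_grayscale(pixels, blood_ref, adv_ref, pixel_density=density)
    roi = norm.trace_to_roi_mask(
        annot["im_upper"], annot["im_lower"], image.pixels.shape,
        pixel_density=density, length_mm=config.roi_length_mm,
    )
    feats = extract_feature_set(image, roi, params=config.texture)

    lines = elastin_mod.read_annotation_file(_resolve(base, row["histology"]))
    emetrics = elastin_mod.elastin_summary(lines)

    findings = plaque_mod.SegmentFindings.from_mapping(str(row["side"]), row)
    rec = {
        "mouse_id": row["mouse_id"], "sex": row["sex"],
        "week": int(row["week"]), "side": row["side"],
        **feats.as_dict(), **emetrics.as_dict(),
        "side_score": plaque_mod.side_score(findings),
        **{s: int(row[s]) for s in plaque_mod.SEGMENTS},
    }
    return rec


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def _cohort_stats(cohort: pd.DataFrame, config: PipelineConfig, out_dir: Path) -> dict[str, Path]:
    outputs = {}
    anova_rows, contrast_rows, spearman_rows = [], [], []
    outcomes = [c for c in FEATURE_COLUMNS + ("n_fibers_weighted",) if c in cohort]
    for outcome in outcomes:
        try:
            res = stats_mod.two_way_anova(cohort, outcome)
        except CarotextureError:
            continue
        for term in res.anova_table.index:
            r = res.anova_table.loc[term]
            anova_rows.append({"outcome": outcome, "term": term,
                               "sum_sq": r.get("sum_sq", np.nan), "df": r["df"],
                               "F": r.get("F", np.nan), "p": r.get("p", np.nan)})
        for sex in sorted(cohort["sex"].unique()):
            for wa, wb in config.contrast_week_pairs:
                try:
                    c = stats_mod.week_contrast_within_sex(res, sex, wa, wb)
                except CarotextureError:
                    continue
                contrast_rows.append({
                    "outcome": outcome, "sex": sex, "week_a": wa, "week_b": wb,
                    "estimate": c.estimate, "se": c.se, "t": c.t, "p": c.p, "df": c.df,
                })
    targets = [c for c in ("n_fibers_weighted", "side_score") if c in cohort]
    for x in [c for c in FEATURE_COLUMNS if c in cohort]:
        for y in targets:
            try:
                tab = stats_mod.spearman_by_sex(cohort, x, y)
            except CarotextureError:
                continue
            for _, r in tab.iterrows():
                spearman_rows.append({"x": x, "y": y, **r.to_dict()})
    for name, rows in (("anova", anova_rows), ("contrasts", contrast_rows),
                       ("spearman", spearman_rows)):
        path = out_dir / f"{name}.csv"
        _write_csv(pd.DataFrame(rows), path)
        outputs[name] = path
    return outputs


def run_pipeline(manifest, config: PipelineConfig | None = None, out_dir="results") -> RunResult:
    """Run the full chain over a manifest and write the results bundle.

    Returns a :class:`RunResult`; ``result.ok`` is False when any record
    was skipped (the CLI turns that into a nonzero exit).
    """
    config = config or PipelineConfig()
    if isinstance(manifest, (str, Path)):
        base = Path(manifest).resolve().parent
        manifest_df = pd.read_csv(manifest)
    else:
        base = Path(".")
        manifest_df = manifest.copy()
    ids = manifest_df[["mouse_id", "week", "side"]].astype(str).agg("/".join, axis=1)
    if ids.duplicated().any():
        raise CarotextureError("manifest ids must be unique per (mouse, week, side)")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, skipped = [], []
    for idx, row in manifest_df.iterrows():
        try:
            records.append(_process_record(row, base, config))
        except (CarotextureError, OSError, KeyError, json.JSONDecodeError) as exc:
            skipped.append({"row": int(idx), "mouse_id": str(row.get("mouse_id")),
                            "side": str(row.get("side")), "error": str(exc)})
    cohort = pd.DataFrame(records)
    outputs: dict[str, Path] = {}
    if not cohort.empty:
        id_cols = ["mouse_id", "sex", "week", "side"]
        _write_csv(cohort[id_cols + list(FEATURE_COLUMNS) + ["roi_px"]],
                   out_dir / "features.csv")
        _write_csv(cohort[id_cols + list(ELASTIN_COLUMNS) + ["n_lines"]],
                   out_dir / "elastin.csv")
        _write_csv(cohort[id_cols + list(plaque_mod.SEGMENTS) + ["side_score"]],
                   out_dir / "plaque.csv")
        _write_csv(cohort, out_dir / "cohort.csv")
        outputs = {name: out_dir / f"{name}.csv"
                   for name in ("features", "elastin", "plaque", "cohort")}
        outputs.update(_cohort_stats(cohort, config, out_dir))
    log = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_records": int(len(manifest_df)),
        "n_processed": int(len(records)),
        "skipped": skipped,
        "outputs": {k: str(v.name) for k, v in sorted(outputs.items())},
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=1, sort_keys=True))
    outputs["run_log"] = log_path
    return RunResult(out_dir=out_dir, n_records=len(manifest_df),
                     n_processed=len(records), skipped=skipped, outputs=outputs)


# ---------------------------------------------------------------------------
# synthetic study inputs (phantom images + annotations + manifest on disk)


def write_synthetic_study(
    out_dir,
    n_per_sex: int = 5,
    weeks=(6, 16, 24),
    seed: int = 0,
    image_format: str = "png",
) -> Path:
    """Write a complete synthetic study a manifest run can consume.

    For every mouse-side-week: a wall phantom image, its frame
    annotation JSON (reference-region polygons inside the true lumen and
    adventitia bands, wall traces on the true band edges) and a
    histology line-annotation JSON generated from the phantom truth.
    Plaque flags accumulate with age.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    weeks = tuple(weeks)
    rows = []
    for sex in ("M", "F"):
        for m in range(1, n_per_sex + 1):
            for week in weeks:
                for side in ("left", "right"):
                    sub_seed = int(rng.integers(0, 2**31 - 1))
                    wk_idx = weeks.index(week)
                    spec = synth.PhantomSpec(
                        n_lamellae=max(2, 5 - wk_idx),
                        lamella_contrast=40.0 + 10.0 * wk_idx,
                        seed=sub_seed,
                    )
                    image, truth = synth.generate_wall_phantom(spec)
                    stem = f"{sex}{m}_w{week}_{side}"
                    img_path = out_dir / f"{stem}.{image_format}"
                    cio.write_image(img_path, image.pixels)

                    h, w = image.pixels.shape
                    top, bottom = spec.wall_band
                    blood_poly = [[4, 4], [w - 5, 4], [w - 5, top - 6], [4, top - 6]]
                    adv_poly = [[4, bottom + 5], [w - 5, bottom + 5],
                                [w - 5, h - 5], [4, h - 5]]
                    upper = [[2, top], [w - 3, top]]
                    lower = [[2, bottom], [w - 3, bottom]]
                    annot_path = out_dir / f"{stem}.json"
                    cio.write_image_annotation(
                        annot_path, blood_poly, adv_poly, upper, lower,
                        pixel_density_per_mm=spec.pixel_density,
                    )

                    lines = synth.generate_line_annotations(
                        truth, n_lines=3, jitter_um=1.0,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    hist_path = out_dir / f"{stem}_elastin.json"
                    elastin_mod.write_annotation_file(hist_path, lines)

                    n_plaque = {6: 0, 16: int(sex == "M"), 24: 2}.get(week, 0)
                    flags = [1] * n_plaque + [0] * (4 - n_plaque)
                    rows.append({
                        "mouse_id": f"{sex}{m}", "sex": sex, "week": week, "side": side,
                        "image": img_path.name, "annot": annot_path.name,
                        "histology": hist_path.name,
                        **dict(zip(plaque_mod.SEGMENTS, flags)),
                    })
    manifest_path = out_dir / "manifest.csv"
    _write_csv(pd.DataFrame(rows), manifest_path)
    return manifest_path
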