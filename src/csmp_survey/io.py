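"""Tabular I/O, run configuration, and the end-to-end pipeline.

CSV with a header row is the single interchange format (UTF-8, "."
decimal, scientific notation accepted); censored cells are written and
read as ``LDL`` with an empty sigma, matching the survey tables' dialect.
Dates are ISO-8601 on output; the ``YYYY/M/D`` dialect is accepted on
input. Every file this module writes starts with comment lines embedding
the tool version, the run seed, and a hash of the configuration, so any
output can be traced to the run that produced it; readers skip ``#``
lines.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
import yaml

from . import __version__
from .nuclides import ACCIDENT_DATE, Activity, CS134, CS137, decay_correct, parse_date
from .sizing import SizeModel, size_particle
from .survey import (
    MaskPair,
    MaskRecord,
    ParticleRecord,
    ResidenceRecord,
    collection_efficiency,
    count_particles,
    csmp_fraction,
    distance_regression,
    efficiency_summary,
    frequency_by_activity_class,
)
from .synthetic import SurveyConfig, SurveyDataset, generate_survey, recover_and_score

__all__ = [
    "MalformedTableError",
    "RunConfig",
    "read_masks",
    "read_particles",
    "read_pairs",
    "read_residences",
    "write_table",
    "read_table",
    "run_pipeline",
]

logger = logging.getLogger("csmp_survey")

_CENSOR_TOKENS = {"LDL", "ldl", "-", "–", ""}


class MalformedTableError(ValueError):
    """A row failed validation; carries all collected row errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors[:5]) + ("..." if len(errors) > 5 else ""))


def _parse_activity(
    row: pd.Series,
    prefix: str,
    nuclide,
    reference_date: datetime.date,
    default_limit: float | None = None,
) -> Activity:
    raw = str(row.get(f"{prefix}_bq", "")).strip()
    censored_flag = str(row.get(f"{prefix}_censored", "")).strip().lower() in {"true", "1", "yes"}
    limit_raw = str(row.get(f"{prefix}_limit_bq", "")).strip()
    limit = float(limit_raw) if limit_raw not in _CENSOR_TOKENS else default_limit
    if raw in _CENSOR_TOKENS or censored_flag:
        if limit is None:
            raise ValueError(f"censored {prefix} value without a detection limit")
        return Activity(nuclide=nuclide, reference_date=reference_date, censored=True, detection_limit=limit)
    sigma_raw = str(row.get(f"{prefix}_sigma", "")).strip()
    return Activity(
        nuclide=nuclide,
        reference_date=reference_date,
        value=float(raw),
        sigma=float(sigma_raw) if sigma_raw not in _CENSOR_TOKENS else 0.0,
        detection_limit=limit,
    )


def read_table(path) -> pd.DataFrame:
    """Read an interchange CSV, skipping ``#`` provenance header lines."""
    return pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)


def _collect(rows: Iterable, parse, skip_bad_rows: bool, label: str):
    records, errors = [], []
    for idx, row in rows:
        try:
            records.append(parse(row))
        except Exception as exc:  # noqa: BLE001 - row-level errors are collected
            errors.append(f"{label} row {idx}: {exc}")
    if errors:
        for e in errors:
            logger.error(e)
        if not skip_bad_rows:
            raise MalformedTableError(errors)
    return records


def read_masks(
    path,
    skip_bad_rows: bool = False,
    default_limit_bq: float = 0.070,
) -> list[MaskRecord]:
    df = read_table(path)
    seen: set[str] = set()

    def parse(row: pd.Series) -> MaskRecord:
        mask_id = row["mask_id"].strip()
        if mask_id in seen:
            raise ValueError(f"duplicate mask_id {mask_id!r}")
        seen.add(mask_id)
        worn = parse_date(row["worn_date"])
        return MaskRecord(
            mask_id=mask_id,
            residence_id=row["residence_id"].strip(),
            person_id=row["person_id"].strip(),
            worn_date=worn,
            mask_type=row["mask_type"].strip().lower(),
            a134=_parse_activity(row, "a134", CS134, worn, default_limit_bq),
            a137=_parse_activity(row, "a137", CS137, worn, default_limit_bq),
        )

    return _collect(df.iterrows(), parse, skip_bad_rows, "masks")


def read_particles(
    path,
    skip_bad_rows: bool = False,
    default_limit_bq: float = 0.00577,
) -> list[ParticleRecord]:
    df = read_table(path)
    seen: set[str] = set()

    def parse(row: pd.Series) -> ParticleRecord:
        pid = row["particle_id"].strip()
        if pid in seen:
            raise ValueError(f"duplicate particle_id {pid!r}")
        seen.add(pid)
        ref = parse_date(row["reference_date"])
        return ParticleRecord(
            particle_id=pid,
            mask_id=row["mask_id"].strip(),
            a134=_parse_activity(row, "a134", CS134, ref, default_limit_bq),
            a137=_parse_activity(row, "a137", CS137, ref, default_limit_bq),
            previously_reported=str(row.get("previously_reported", "false")).strip().lower()
            in {"true", "1", "yes"},
        )

    return _collect(df.iterrows(), parse, skip_bad_rows, "particles")


def read_pairs(path, masks: list[MaskRecord], skip_bad_rows: bool = False) -> list[MaskPair]:
    df = read_table(path)
    by_id = {m.mask_id: m for m in masks}

    def parse(row: pd.Series) -> MaskPair:
        return MaskPair(outer=by_id[row["outer_mask_id"].strip()], inner=by_id[row["inner_mask_id"].strip()])

    return _collect(df.iterrows(), parse, skip_bad_rows, "pairs")


def read_residences(path, skip_bad_rows: bool = False) -> list[ResidenceRecord]:
    df = read_table(path)

    def parse(row: pd.Series) -> ResidenceRecord:
        return ResidenceRecord(
            residence_id=row["residence_id"].strip(),
            distance_km=float(row["distance_km"]),
            construction=row.get("construction", "wood").strip().lower() or "wood",
        )

    return _collect(df.iterrows(), parse, skip_bad_rows, "residences")


def _provenance_header(seed: int | None, config_hash: str) -> str:
    return (
        f"# csmp-survey {__version__}\n"
        f"# seed={seed if seed is not None else 'none'} config_hash={config_hash}\n"
    )


def config_digest(obj: Any) -> str:
    """Short stable hash of a (dataclass or dict) configuration."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed: int | None = None, config_hash: str = "none") -> None:
    """Write an interchange CSV with the provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_header(seed, config_hash))
        df.to_csv(fh, index=False)


@dataclass
class RunConfig:
    """Configuration for one end-to-end run.

    Either real input tables (masks/particles/pairs/residences CSVs) or a
    synthetic survey config; outputs land in ``output_dir`` with the seed
    and config hash stamped in every file header.
    """

    output_dir: str = "csmp_survey_out"
    seed: int = 0
    masks_path: str | None = None
    particles_path: str | None = None
    pairs_path: str | None = None
    residences_path: str | None = None
    synthetic: SurveyConfig | None = None
    size_model: SizeModel = field(default_factory=SizeModel)
    mask_detection_limit_bq: float = 0.070
    particle_detection_limit_bq: float = 0.00577
    frequency_class_edges: tuple[float, ...] = (0.07, 1.0, 10.0, 100.0, 1000.0, 10000.0)
    fixed_regression_slope: float | None = None
    skip_bad_rows: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        synth = payload.pop("synthetic", None)
        size = payload.pop("size_model", None)
        cfg = cls(**payload)
        if synth is not None:
            cfg.synthetic = SurveyConfig(**synth)
        if size is not None:
            cfg.size_model = SizeModel(**size)
        return cfg


def _records_from_dataset(dataset: SurveyDataset, cfg: RunConfig):
    """Round the synthetic tables through the readers' row parsing."""
    import io as _io

    def _via(df: pd.DataFrame, reader, **kw):
        buf = _io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return reader(buf, **kw)

    masks = _via(dataset.masks, read_masks, default_limit_bq=cfg.mask_detection_limit_bq)
    particles = _via(dataset.particles, read_particles, default_limit_bq=cfg.particle_detection_limit_bq)
    pairs = _via(dataset.pairs, read_pairs, masks=masks)
    residences = _via(dataset.residences, read_residences)
    return masks, particles, pairs, residences


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run the full analysis and write the report bundle.

    Stages: load (or generate) the survey, decay-correct particle
    activities to 2011-03-11, size the particles, compute pair collection
    efficiencies and their summary, particle counts, the CsMP frequency
    table by mask-activity class, and the distance regression. Outputs:
    one CSV per report table plus ``summary.json``. Idempotent for a
    fixed configuration and seed.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash the analytic configuration only, so reruns into a different
    # directory are recognisably the same run
    analytic = {k: v for k, v in dataclasses.asdict(cfg).items() if k != "output_dir"}
    digest = config_digest(analytic)
    dataset = None
    stage = "load"
    try:
        if cfg.synthetic is not None:
            stage = "simulate"
            dataset = generate_survey(cfg.synthetic)
            masks, particles, pairs, residences = _records_from_dataset(dataset, cfg)
            for name, df in (
                ("masks", dataset.masks),
                ("particles", dataset.particles),
                ("pairs", dataset.pairs),
                ("residences", dataset.residences),
            ):
                write_table(df, outdir / f"{name}.csv", cfg.seed, digest)
            dataset.truth.to_json(outdir / "truth.json")
        else:
            if cfg.masks_path is None:
                raise ValueError("need either input table paths or a synthetic config")
            masks = read_masks(cfg.masks_path, cfg.skip_bad_rows, cfg.mask_detection_limit_bq)
            particles = (
                read_particles(cfg.particles_path, cfg.skip_bad_rows, cfg.particle_detection_limit_bq)
                if cfg.particles_path
                else []
            )
            pairs = read_pairs(cfg.pairs_path, masks, cfg.skip_bad_rows) if cfg.pairs_path else []
            residences = read_residences(cfg.residences_path, cfg.skip_bad_rows) if cfg.residences_path else []

        summary: dict[str, Any] = {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": digest,
        }

        stage = "size"
        size_rows = []
        for p in particles:
            if p.a137.censored:
                continue
            a2011 = decay_correct(p.a137, ACCIDENT_DATE)
            est = size_particle(p.a137, cfg.size_model)
            size_rows.append(
                {
                    "particle_id": p.particle_id,
                    "a137_2011_bq": a2011.value,
                    "a137_2011_sigma": a2011.sigma,
                    "volume_cm3": est.volume_cm3,
                    "diameter_um": est.diameter_um,
                }
            )
        sizes = pd.DataFrame(size_rows)
        write_table(sizes, outdir / "particle_sizes.csv", cfg.seed, digest)

        stage = "efficiency"
        eff_results = []
        for pair in pairs:
            try:
                eff_results.append(collection_efficiency(pair))
            except Exception as exc:  # censored pairs are skipped, not fatal
                logger.warning("pair %s/%s skipped: %s", pair.outer.mask_id, pair.inner.mask_id, exc)
        if eff_results:
            s = efficiency_summary(eff_results)
            summary["efficiency"] = {
                "n_total": s.n_total,
                "n_significant": s.n_significant,
                "max_pct": s.max_pct,
                "min_pct": s.min_pct,
                "mean_pct": s.mean_pct,
            }

        stage = "counts"
        counts = count_particles(particles)
        summary["particles"] = {
            "n_total": counts.n_total,
            "n_new": counts.n_new,
            "n_masks_with_new": counts.n_masks_with_new,
        }

        stage = "fractions"
        mask_by_id = {m.mask_id: m for m in masks}
        frac_rows = []
        for p in particles:
            m = mask_by_id.get(p.mask_id)
            if m is None or m.a137.censored or p.a137.censored:
                continue
            fr = csmp_fraction(p, m)
            frac_rows.append(
                {"particle_id": p.particle_id, "mask_id": p.mask_id, "fraction_pct": fr.percent}
            )
        write_table(pd.DataFrame(frac_rows), outdir / "csmp_fractions.csv", cfg.seed, digest)

        stage = "frequency"
        freq = frequency_by_activity_class(masks, particles, cfg.frequency_class_edges)
        write_table(freq, outdir / "frequency_by_class.csv", cfg.seed, digest)

        stage = "regression"
        if residences:
            dist = {r.residence_id: r.distance_km for r in residences}
            pts = [
                (dist[m.residence_id], m.a137.value)
                for m in masks
                if m.residence_id in dist and not m.a137.censored and m.a137.value > 0
            ]
            if len(pts) >= 3:
                fit = distance_regression(pts, cfg.fixed_regression_slope)
                summary["distance_regression"] = {
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "slope_stderr": fit.slope_stderr,
                    "n_points": len(pts),
                }

        if dataset is not None:
            stage = "recovery"
            rep = recover_and_score(dataset)
            summary["recovery"] = dataclasses.asdict(rep)

        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, default=str)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
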