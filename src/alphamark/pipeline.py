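"""End-to-end cohort pipeline: simulate or ingest -> preprocess ->
spectra -> anchors/bands/ratios -> coherence -> stratification -> stats.

The pipeline is deliberately a thin composition of the library stages so
that a run is fully described by its config; in simulate mode re-running
the same config is bit-identical (the manifest carries no timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coherence import coherence_profile
from .errors import AlphamarkError, ConfigError
from .io import read_recording
from .montage import PAIR_SETS
from .preprocess import (Recording, common_average_reference,
                         reject_artifacts, segment_epochs)
from .spectral import (BAND_NAMES, AnchorFrequencies, band_powers,
                       build_band_scheme, detect_iaf, detect_tf,
                       grand_average_spectrum, relative_power, welch_psd)
from .stats import (TertileCutoffs, classify_tertile, derive_tertiles,
                    group_summary, mixed_anova, pearson_r)
from .synth import CohortSpec, generate_cohort

logger = logging.getLogger("alphamark")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    mode: str = "simulate"                  # simulate | edf-dir
    input_dir: str | None = None            # edf-dir mode
    out_dir: str = "alphamark-out"
    master_seed: int = 0
    # simulate mode
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"low": 18, "middle": 38, "high": 18})
    duration: float = 300.0
    coupling: list = field(default_factory=list)
    # preprocessing
    epoch_length: float = 2.0
    amp_limit: float = 100.0
    grad_limit: float = 50.0
    # spectral
    tf_search_lo: float = 3.0
    b1_hi: float = 19.2
    b2_hi: float = 32.4
    # stratification: fixed published cutoffs or empirical tertiles
    cutoff_mode: str = "fixed"              # fixed | empirical
    low_hi: float = 1.0
    high_lo: float = 1.17
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("simulate", "edf-dir"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "edf-dir":
            if not self.input_dir:
                raise ConfigError("edf-dir mode requires input_dir")
            path = Path(self.input_dir)
            if not path.is_dir():
                raise ConfigError(f"input_dir {path} does not exist")
            if not sorted(path.glob("*.edf")):
                raise ConfigError(f"no .edf files in {path}")
        if self.cutoff_mode not in ("fixed", "empirical"):
            raise ConfigError(f"unknown cutoff_mode {self.cutoff_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageFailure(AlphamarkError):
    """A pipeline stage failed for a specific subject."""

    def __init__(self, stage: str, subject: str, cause: Exception):
        self.stage, self.subject, self.cause = stage, subject, cause
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {cause}")


def process_subject(rec: Recording, cfg: PipelineConfig) -> dict:
    """Run one subject through preprocessing, spectra, and coherence."""
    sid = rec.subject_id
    stage = "preprocess"
    try:
        car = common_average_reference(rec)
        es = segment_epochs(car, cfg.epoch_length)
        es = reject_artifacts(es, cfg.amp_limit, cfg.grad_limit)
        logger.info("%s: %d/%d epochs kept", sid, es.n_kept, es.n_epochs)
        stage = "spectra"
        ps = welch_psd(es)
        avg = grand_average_spectrum(ps)
        iaf = detect_iaf(avg)
        tf = detect_tf(avg, iaf, cfg.tf_search_lo)
        anchors = AnchorFrequencies(tf=tf, iaf=iaf)
        scheme = build_band_scheme(anchors, cfg.b1_hi, cfg.b2_hi)
        bp = band_powers(relative_power(ps), scheme, subject_id=sid,
                         anchors=anchors)
        stage = "coherence"
        coh = coherence_profile(es, scheme)
        coh.insert(0, "subject", sid)
    except AlphamarkError as exc:
        raise StageFailure(stage, sid, exc) from exc
    return {"band_power": bp, "coherence": coh,
            "epochs_total": es.n_epochs, "epochs_kept": es.n_kept}


def _band_table(results: list[dict]) -> pd.DataFrame:
    rows = []
    for res in results:
        bp = res["band_power"]
        row = {"subject": bp.subject_id, "tf": bp.anchors.tf,
               "iaf": bp.anchors.iaf}
        row.update({b: bp.rel_power[b] for b in BAND_NAMES})
        row["alpha3_alpha2"] = bp.alpha3_alpha2
        row["theta_gamma"] = bp.theta_gamma
        rows.append(row)
    return pd.DataFrame(rows)


def _anova_tables(coh_all: pd.DataFrame, groups_by_subject: pd.Series) -> pd.DataFrame:
    """One three-way interaction row per pair set."""
    rows = []
    for set_name in PAIR_SETS:
        sub = coh_all[coh_all.pair_set == set_name]
        wide = sub.pivot_table(index="subject", columns=["band", "pair"],
                               values="coherence", sort=True)
        subjects = wide.index.to_numpy()
        n_band = sub.band.nunique()
        n_pair = sub.pair.nunique()
        values = wide.to_numpy().reshape(len(subjects), n_band, n_pair)
        groups = groups_by_subject.loc[subjects].to_numpy()
        counts = pd.Series(groups).value_counts()
        if (counts < 2).any() or len(counts) < 2:
            logger.warning("skipping ANOVA for %s: groups too small", set_name)
            continue
        res = mixed_anova(values, groups)
        res["pair_set"] = set_name
        rows.append(res)
    return pd.DataFrame(rows)


def _correlation_table(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between EEG measures and covariates."""
    measures = [c for c in ("alpha3_alpha2", "theta_gamma", "theta")
                if c in records.columns]
    covs = [c for c in ("age", "mmse", "education") if c in records.columns]
    rows = []
    for m in measures:
        for c in covs:
            try:
                res = pearson_r(records[m], records[c])
            except ValueError:
                continue
            rows.append({"measure": m, "covariate": c, **res})
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a dict of output paths.

    Outputs under ``cfg.out_dir``: band_powers.csv, coherence.csv,
    group_summary.csv, anova.csv, correlations.csv, manifest.json (and
    truth.csv in simulate mode). On a stage failure the partial outputs
    written so far are retained next to a failure manifest.
    """
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20),
                        format="%(name)s %(levelname)s %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if cfg.mode == "simulate":
        cohort = CohortSpec(
            group_sizes=dict(cfg.group_sizes), duration=cfg.duration,
            coupling=[((a, b), m) for (a, b), m in
                      ((tuple(p[0]), p[1]) for p in cfg.coupling)],
            master_seed=cfg.master_seed)
        recordings, truth = generate_cohort(cohort)
        truth.to_csv(out / "truth.csv", index=False)
    else:
        paths = sorted(Path(cfg.input_dir).glob("*.edf"))
        recordings = [read_recording(p, "edf") for p in paths]

    results = []
    try:
        for rec in recordings:
            results.append(process_subject(rec, cfg))
    except StageFailure as exc:
        _write_partial(out, cfg, results, exc)
        raise

    bands = _band_table(results)
    coh_all = pd.concat([r["coherence"] for r in results], ignore_index=True)

    if cfg.cutoff_mode == "fixed":
        cutoffs = TertileCutoffs(cfg.low_hi, cfg.high_lo)
    else:
        cutoffs = derive_tertiles(bands.alpha3_alpha2)
    bands["group"] = [classify_tertile(r, cutoffs) for r in bands.alpha3_alpha2]

    records = bands
    if truth is not None:
        records = bands.merge(
            truth.drop(columns=["group"]), on="subject", how="left")

    summary_cols = [c for c in ("age", "education", "mmse", "alpha3_alpha2")
                    if c in records.columns]
    summary = group_summary(records, summary_cols)
    anova = _anova_tables(coh_all, records.set_index("subject")["group"])
    correlations = _correlation_table(records)

    paths = {}
    for name, frame in [("band_powers", bands), ("coherence", coh_all),
                        ("group_summary", summary), ("anova", anova),
                        ("correlations", correlations)]:
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = str(p)

    manifest = {
        "alphamark_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(cfg),
        "n_subjects": len(results),
        "epochs": {r["band_power"].subject_id: {
            "total": r["epochs_total"], "kept": r["epochs_kept"]}
            for r in results},
        "cutoffs": {"low_hi": cutoffs.low_hi, "high_lo": cutoffs.high_lo},
        "status": "ok",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = str(out / "manifest.json")
    if truth is not None:
        paths["truth"] = str(out / "truth.csv")
    return paths


def _write_partial(out: Path, cfg: PipelineConfig, results: list,
                   exc: StageFailure) -> None:
    if results:
        _band_table(results).to_csv(out / "band_powers.partial.csv", index=False)
    manifest = {
        "alphamark_version": __version__,
        "config": asdict(cfg),
        "status": "failed",
        "failed_stage": exc.stage,
        "failed_subject": exc.subject,
        "error": str(exc.cause),
        "subjects_completed": len(results),
    }
    (out / "failure_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
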