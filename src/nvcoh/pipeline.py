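"""End-to-end analysis pipeline.

Composes the library: preprocess each subject's channels, wavelet-transform
them, compute phase coherence (or power) for every requested channel pair,
derive inter-subject surrogate thresholds, band-average into subject x pair
summary tables, and compare the two groups pair by pair with rank-sum,
permutation-confirmation and binomial multiplicity statistics.

Driven by a single config (YAML on disk or `PipelineConfig` in memory);
identical config and seed give identical outputs, recorded in a run
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bandstats import (
    BandSummaryTable,
    FrequencyBand,
    band_by_name,
    build_summary_table,
    cardiovascular_bands,
)
from .coherence import (
    effective_coherence,
    surrogate_threshold,
    wavelet_phase_coherence,
)
from .groupstats import GroupComparison, MultiplicitySummary, compare_groups
from .preprocess import PreprocessConfig, preprocess_channel
from .ridge import CARDIAC_BAND, RESPIRATORY_BAND, instantaneous_rate
from .signal_io import Recording, ValidationError, read_recording
from .timefreq import make_log_grid, wavelet_transform

logger = logging.getLogger(__name__)

ANALYSES = (
    "fnirs_power",
    "eeg_power",
    "fnirs_fnirs_wpc",
    "eeg_eeg_wpc",
    "fnirs_eeg_wpc",
    "ihr_fnirs_wpc",
    "irr_fnirs_wpc",
    "resp_fnirs_wpc",
    "resp_ihr_wpc",
)


@dataclass
class PipelineConfig:
    analyses: tuple[str, ...] = ("fnirs_fnirs_wpc",)
    group_a: str = "P"
    group_b: str = "PC"
    grid_fmin: float = 0.007
    grid_fmax: float = 4.0
    grid_n: int = 273
    wavelet: str = "morlet"
    resolution: float = 1.0
    bands: tuple[str, ...] = ()
    beta_hi: float = 22.0
    detrend_order: int = 3
    band_lo: float = 0.007
    band_hi: float = 4.0
    target_fs: float | None = None
    segment_length: float = 1200.0
    n_surrogates: int = 176
    n_permutations: int | None = 16000
    percentile: float = 95.0
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "nvcoh_results"
    manifest: str | None = None  # TSV: subject <tab> group <tab> path

    def __post_init__(self) -> None:
        if not self.analyses:
            raise ValidationError("config: 'analyses' must be non-empty")
        for a in self.analyses:
            if a not in ANALYSES:
                raise ValidationError(
                    f"config: unknown analysis {a!r}; choose from {ANALYSES}"
                )
        if not self.bands:
            self.bands = tuple(b.name for b in cardiovascular_bands())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ValidationError(f"config {path}: top level must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise ValidationError(f"config {path}: unknown keys {sorted(bad)}")
        for key in ("analyses", "bands"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        try:
            return cls(**doc)
        except TypeError as exc:
            raise ValidationError(f"config {path}: {exc}") from exc

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def band_objects(self) -> list[FrequencyBand]:
        return [band_by_name(name, self.beta_hi) for name in self.bands]


def study_preset(**overrides) -> PipelineConfig:
    """The full-scale study configuration: 0.007-4 Hz, 273 frequencies,
    176 surrogates, 16 000 permutations, 95th percentile, alpha 0.05."""
    return PipelineConfig(**overrides)


def load_cohort_from_manifest(manifest_path: str | Path) -> list[Recording]:
    rows = pd.read_csv(manifest_path, sep="\t")
    needed = {"subject", "group", "path"}
    if not needed <= set(rows.columns):
        raise ValidationError(f"manifest must have columns {sorted(needed)}")
    base = Path(manifest_path).parent
    cohort = []
    for _, row in rows.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        rec = read_recording(p)
        rec.subject_id = str(row["subject"])
        rec.group_label = str(row["group"])
        cohort.append(rec)
    return cohort


def _analysis_channels(rec: Recording, role: str, config: PipelineConfig) -> dict[str, np.ndarray]:
    """Channel series for one side of an analysis, keyed by label.

    Derived roles: ``ihr``/``irr`` run ridge rate extraction on the ECG /
    respiration channel first.
    """
    if role == "fnirs":
        return {c.label: c.samples for c in rec.channels if c.modality == "FNIRS"}
    if role == "eeg":
        return {c.label: c.samples for c in rec.channels if c.modality == "EEG"}
    if role == "resp":
        return {c.label: c.samples for c in rec.channels if c.modality == "RESP"}
    if role == "ihr":
        ecg = [c for c in rec.channels if c.modality == "ECG"]
        if not ecg:
            return {}
        rate = instantaneous_rate(ecg[0].samples, rec.fs, *CARDIAC_BAND, source="ECG")
        return {"IHR": rate.samples}
    if role == "irr":
        resp = [c for c in rec.channels if c.modality == "RESP"]
        if not resp:
            return {}
        rate = instantaneous_rate(
            resp[0].samples, rec.fs, *RESPIRATORY_BAND, source="RESP"
        )
        return {"IRR": rate.samples}
    raise ValueError(role)


_ANALYSIS_ROLES = {
    "fnirs_power": ("fnirs", None),
    "eeg_power": ("eeg", None),
    "fnirs_fnirs_wpc": ("fnirs", "fnirs"),
    "eeg_eeg_wpc": ("eeg", "eeg"),
    "fnirs_eeg_wpc": ("fnirs", "eeg"),
    "ihr_fnirs_wpc": ("ihr", "fnirs"),
    "irr_fnirs_wpc": ("irr", "fnirs"),
    "resp_fnirs_wpc": ("resp", "fnirs"),
    "resp_ihr_wpc": ("resp", "ihr"),
}


@dataclass
class AnalysisResult:
    analysis: str
    tables: dict[str, dict[str, BandSummaryTable]]   # group -> band -> table
    comparisons: dict[str, list[GroupComparison]]    # band -> per-pair stats
    summaries: dict[str, MultiplicitySummary]        # band -> multiplicity


def _preprocess_for_analysis(
    x: np.ndarray, fs: float, config: PipelineConfig
) -> tuple[np.ndarray, float]:
    pc = PreprocessConfig(
        detrend_order=config.detrend_order,
        band_lo=config.band_lo,
        band_hi=min(config.band_hi, 0.49 * fs),
        target_fs=config.target_fs,
        segment_length=config.segment_length,
    )
    n_seg = min(int(round(config.segment_length * fs)), x.size)
    return preprocess_channel(x[:n_seg], fs, pc)


def run_analysis(
    cohort: list[Recording], analysis: str, config: PipelineConfig,
    rng: np.random.Generator,
) -> AnalysisResult:
    role_a, role_b = _ANALYSIS_ROLES[analysis]
    grid = make_log_grid(config.grid_fmin, config.grid_fmax, config.grid_n)
    bands = [
        b for b in config.band_objects()
        if grid.band_indices(b.lo, b.hi).size > 0
    ]

    # preprocess + transform every needed channel once, per subject
    tfrs: dict[str, dict[str, object]] = {}
    for rec in cohort:
        chans = dict(_analysis_channels(rec, role_a, config))
        if role_b and role_b != role_a:
            chans.update(_analysis_channels(rec, role_b, config))
        tfrs[rec.subject_id] = {}
        for label, x in chans.items():
            y, fs_out = _preprocess_for_analysis(x, rec.fs, config)
            tfr = wavelet_transform(
                y, fs_out, grid, config.wavelet, config.resolution
            )
            tfr.coefficients = tfr.coefficients.astype(np.complex64)
            tfrs[rec.subject_id][label] = tfr

    groups = sorted({rec.group_label for rec in cohort})
    subjects_of = {
        g: [rec.subject_id for rec in cohort if rec.group_label == g] for g in groups
    }

    if role_b is None:  # power analysis: one "pair" per channel
        from .timefreq import time_averaged_power

        spectra = {
            sub: {
                label: (grid, time_averaged_power(tfr).power)
                for label, tfr in sub_tfrs.items()
            }
            for sub, sub_tfrs in tfrs.items()
        }
        metric = "power"
    else:
        labels_a = sorted(
            {l for sub in tfrs.values() for l in sub
             if _label_has_role(l, role_a)}
        )
        labels_b = sorted(
            {l for sub in tfrs.values() for l in sub
             if _label_has_role(l, role_b)}
        )
        if role_a == role_b:
            pairs = [
                (a, b) for i, a in enumerate(labels_a) for b in labels_a[i + 1:]
            ]
        else:
            pairs = [(a, b) for a in labels_a for b in labels_b]
        # per-pair surrogate threshold shared by all subjects
        all_subjects = list(tfrs)
        spectra: dict[str, dict[str, tuple]] = {s: {} for s in all_subjects}
        for a, b in pairs:
            have = [s for s in all_subjects if a in tfrs[s] and b in tfrs[s]]
            if len(have) < 2:
                continue
            thr, _ = surrogate_threshold(
                [tfrs[s][a] for s in have],
                [tfrs[s][b] for s in have],
                n_surrogates=min(config.n_surrogates, len(have) * (len(have) - 1)),
                percentile=config.percentile,
                seed=rng,
            )
            for s in have:
                spec = wavelet_phase_coherence(tfrs[s][a], tfrs[s][b])
                eff = effective_coherence(spec, thr)
                spectra[s][f"{a}-{b}"] = (grid, eff.effective)
        metric = "coherence"

    tables: dict[str, dict[str, BandSummaryTable]] = {}
    for g in groups:
        tables[g] = {}
        for band in bands:
            sub_spectra = {s: spectra[s] for s in subjects_of[g]}
            tables[g][band.name] = build_summary_table(sub_spectra, band, metric)

    comparisons: dict[str, list[GroupComparison]] = {}
    summaries: dict[str, MultiplicitySummary] = {}
    if config.group_a in tables and config.group_b in tables:
        for band in bands:
            t1 = tables[config.group_a][band.name]
            t2 = tables[config.group_b][band.name]
            comp, summ = compare_groups(
                t1, t2, n_permutations=config.n_permutations, seed=rng,
                alpha=config.alpha,
            )
            comparisons[band.name] = comp
            summaries[band.name] = summ
    return AnalysisResult(analysis, tables, comparisons, summaries)


def _label_has_role(label: str, role: str) -> bool:
    from .signal_io import infer_modality

    modality = infer_modality(label)
    return {
        "fnirs": modality == "FNIRS",
        "eeg": modality == "EEG",
        "resp": modality == "RESP",
        "ihr": label == "IHR",
        "irr": label == "IRR",
    }[role]


def run_pipeline(
    config: PipelineConfig, cohort: list[Recording] | None = None
) -> dict[str, AnalysisResult]:
    """Run every configured analysis and write the result bundle.

    ``cohort`` may be given directly; otherwise it is loaded from the
    config's manifest.
    """
    t_start = time.time()
    if cohort is None:
        if config.manifest is None:
            raise ValidationError("config: either pass a cohort or set 'manifest'")
        cohort = load_cohort_from_manifest(config.manifest)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    results: dict[str, AnalysisResult] = {}
    outputs: list[str] = []
    for analysis in config.analyses:
        t0 = time.time()
        logger.info("stage %s: starting", analysis)
        try:
            res = run_analysis(cohort, analysis, config, rng)
        except Exception as exc:
            _write_manifest(config, outputs, out, failed_stage=analysis, error=str(exc))
            raise RuntimeError(f"stage {analysis!r} failed: {exc}") from exc
        results[analysis] = res
        for g, per_band in res.tables.items():
            for band_name, table in per_band.items():
                path = out / f"{analysis}_{band_name}_{g}_summary.tsv"
                table.to_tsv(path)
                outputs.append(path.name)
        for band_name, comps in res.comparisons.items():
            path = out / f"{analysis}_{band_name}_comparison.tsv"
            pd.DataFrame(
                [
                    {
                        "pair": c.pair,
                        "p_value": c.p_value,
                        "direction": c.direction,
                        "cohens_d": c.cohens_d,
                        "permutation_confirmed": c.permutation_confirmed,
                        "permutation_quantile": c.permutation_quantile,
                    }
                    for c in comps
                ]
            ).to_csv(path, sep="\t", index=False)
            outputs.append(path.name)
            summ = res.summaries[band_name]
            jpath = out / f"{analysis}_{band_name}_multiplicity.json"
            jpath.write_text(
                json.dumps(
                    {
                        "n_tests": summ.n_tests,
                        "n_significant": summ.n_significant,
                        "alpha": summ.alpha,
                        "binomial_tail_probability": summ.binomial_tail_probability,
                    },
                    indent=2,
                )
            )
            outputs.append(jpath.name)
        logger.info("stage %s: done in %.1f s", analysis, time.time() - t0)

    _write_manifest(config, outputs, out, elapsed=time.time() - t_start)
    return results


def _write_manifest(
    config: PipelineConfig, outputs: list[str], out: Path,
    failed_stage: str | None = None, error: str | None = None,
    elapsed: float | None = None,
) -> None:
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "outputs": outputs,
        "status": "failed" if failed_stage else "complete",
    }
    if failed_stage:
        manifest["failed_stage"] = failed_stage
        manifest["error"] = error
    if elapsed is not None:
        manifest["elapsed_s"] = round(elapsed, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
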