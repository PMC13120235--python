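"""End-to-end orchestration: per-variety model building, limit of
detection, and screening of unknown blends.

For each targeted variety the workflow builds two models from the same
spectral dataset:

* a *qualitative* binary PLS-DA classifier trained on the equal-proportion
  subset design (present vs absent), with a duplex-selected external test
  set, a sweep over the six pre-treatments and a limit of detection read off
  the trituration series;
* a *quantitative* PLS1 regression trained on the samples that contain the
  variety (its proportion as response) with its own independent duplex split
  and pre-treatment sweep.

Screening applies the chosen qualitative model to each unknown sample and
reports a proportion estimate only for positive calls; estimates below the
lowest calibrated proportion carry a "<1%" style marker while the raw value
(possibly negative) is retained.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    CompositionTable,
    SpectraSet,
    ValidationError,
    cut_region,
    write_composition_csv,
    write_spectra_csv,
)
from .evaluation import (
    LODResult,
    SelectionReport,
    estimate_lod,
    sweep_pretreatments,
)
from .preprocess import PretreatmentSpec, default_specs
from .simulate import (
    DEFAULT_TRITURATION_LEVELS,
    GeneratorConfig,
    MixtureDesign,
    build_commercial_design,
    build_full_design,
    generate_endmembers,
    synthesize_spectra,
)
from .split import duplex_split

_EQ_ATOL = 1e-9  # equal-proportion tolerance when deriving design labels


@dataclass(frozen=True)
class WorkflowConfig:
    """Tunables of the per-variety modelling workflow.

    ``test_fraction`` sizes the duplex test set at ``round(f * n)``;
    ``max_lv`` is capped per training set at
    ``n_train - ceil(n_train / n_folds) - 1``.  ``region`` optionally
    restricts spectra (e.g. ``(650, 2000)`` for the mid-IR fingerprint
    region) before splitting and modelling; ``calibration_min`` is the
    lowest calibrated proportion, below which screening estimates are
    flagged.
    """

    test_fraction: float = 0.2
    n_folds: int = 10
    max_lv: int = 15
    sg_window: int = 17
    sg_polyorder: int = 2
    calibration_min: float = 1.0
    lod_levels: tuple = DEFAULT_TRITURATION_LEVELS
    region: tuple | None = None
    seed: int = 0

    def specs(self) -> list[PretreatmentSpec]:
        return default_specs(self.sg_window, self.sg_polyorder)


def derive_design_labels(composition: CompositionTable) -> list[str]:
    """Recover design labels from the proportions alone.

    Rows whose nonzero proportions are all equal belong to the
    equal-proportion subset design (pure/binary/.../senary by count);
    rows with unequal nonzero proportions are trituration-style spikes.
    """
    k_names = {1: "pure", 2: "binary", 3: "ternary", 4: "quaternary",
               5: "quinary", 6: "senary"}
    labels = []
    for row in composition.proportions:
        nz = row[row > 0]
        if np.all(np.abs(nz - nz[0]) <= _EQ_ATOL * max(1.0, nz[0])):
            labels.append(k_names.get(len(nz), f"{len(nz)}-component"))
        else:
            labels.append("trituration")
    return labels


@dataclass(eq=False)
class VarietyResult:
    """All models and reports for one targeted variety."""

    variety: str
    qualitative: SelectionReport
    quantitative: SelectionReport
    lod: LODResult | None
    qual_split: tuple       # (train ids, test ids)
    quant_split: tuple
    n_qualitative: int
    n_quantitative: int


def _round_test_size(fraction: float, n: int) -> int:
    return max(1, int(round(fraction * n)))


def run_variety_workflow(
    spectra: SpectraSet,
    composition: CompositionTable,
    variety: str,
    config: WorkflowConfig = WorkflowConfig(),
    design_labels: list[str] | None = None,
) -> VarietyResult:
    """Build, select and characterise both models for one variety.

    The duplex splits are computed on the raw (only region-cut) spectra —
    the original spectral data space — and are independent between the
    classification and regression branches, whose sample sets differ.
    """
    if variety not in composition.varieties:
        raise ValidationError(f"variety {variety!r} not in composition table")
    if spectra.sample_ids != composition.sample_ids:
        raise ValidationError("spectra and composition sample ids differ")
    labels = (
        list(design_labels)
        if design_labels is not None
        else derive_design_labels(composition)
    )
    if config.region is not None:
        spectra = cut_region(spectra, *config.region)
    prop = composition.proportion_of(variety)
    v_idx = composition.varieties.index(variety)

    # qualitative branch: equal-proportion subset design, present vs absent
    subset_mask = np.array(
        [lab not in ("trituration", "commercial") for lab in labels]
    )
    qual_s = spectra.select(subset_mask)
    qual_y = (prop[subset_mask] > 0).astype(float)
    split_q = duplex_split(qual_s.absorbance,
                           _round_test_size(config.test_fraction, qual_s.n_samples))
    tr_q, te_q = qual_s.select(split_q.train_indices), qual_s.select(split_q.test_indices)
    qual = sweep_pretreatments(
        tr_q, te_q,
        qual_y[split_q.train_indices], qual_y[split_q.test_indices],
        config.specs(), task="classification",
        max_lv=config.max_lv, n_folds=config.n_folds, seed=config.seed,
    )

    # limit of detection from this variety's trituration series
    lod = None
    trit_rows = [
        i for i, lab in enumerate(labels)
        if lab == "trituration"
        and int(np.argmin(np.where(composition.proportions[i] > 0,
                                   composition.proportions[i], np.inf))) == v_idx
    ]
    if trit_rows:
        trit_rows = sorted(trit_rows, key=lambda i: prop[i])
        entry = qual.chosen_entry
        lod = estimate_lod(
            entry.model, entry.pretreatment,
            spectra.select(trit_rows), [prop[i] for i in trit_rows], variety,
        )

    # quantitative branch: every sample containing the variety
    pos_mask = np.array(
        [p > 0 and lab != "commercial" for p, lab in zip(prop, labels)]
    )
    quant_s = spectra.select(pos_mask)
    quant_y = prop[pos_mask]
    split_r = duplex_split(quant_s.absorbance,
                           _round_test_size(config.test_fraction, quant_s.n_samples))
    tr_r, te_r = quant_s.select(split_r.train_indices), quant_s.select(split_r.test_indices)
    quant = sweep_pretreatments(
        tr_r, te_r,
        quant_y[split_r.train_indices], quant_y[split_r.test_indices],
        config.specs(), task="regression",
        max_lv=config.max_lv, n_folds=config.n_folds, seed=config.seed + 1,
    )

    return VarietyResult(
        variety, qual, quant, lod,
        ([qual_s.sample_ids[i] for i in split_q.train_indices],
         [qual_s.sample_ids[i] for i in split_q.test_indices]),
        ([quant_s.sample_ids[i] for i in split_r.train_indices],
         [quant_s.sample_ids[i] for i in split_r.test_indices]),
        qual_s.n_samples, quant_s.n_samples,
    )


# ----------------------------------------------------------------------
# screening

def format_screening_value(positive: bool, estimate: float | None,
                           calibration_min: float) -> str:
    """Render one screening cell: "-" for a negative call, "<1%" below the
    calibrated range (raw value kept separately), else the rounded percent."""
    if not positive:
        return "-"
    if estimate < calibration_min:
        return f"<{calibration_min:g}%"
    return f"{estimate:.1f}%"


@dataclass(eq=False)
class ScreeningReport:
    """Long-format screening outcome: one row per (sample, variety).

    ``estimate`` is NaN wherever the qualitative call is negative — a
    quantitative value is never produced for a negative call.  ``display``
    renders the compact table form.
    """

    table: pd.DataFrame
    calibration_min: float

    def pivot(self) -> pd.DataFrame:
        """Wide display table (varieties x samples)."""
        return self.table.pivot(index="variety", columns="sample_id",
                                values="display")

    def errors_vs(self, declared: pd.DataFrame) -> pd.DataFrame:
        """Absolute differences |estimate - declared| for positive calls.

        ``declared`` is a samples x varieties frame of reference
        percentages; pairs without a positive call or a declared value are
        dropped.
        """
        rows = []
        for _, r in self.table.iterrows():
            if not r["positive"]:
                continue
            try:
                ref = float(declared.loc[r["sample_id"], r["variety"]])
            except KeyError:
                continue
            if math.isnan(ref):
                continue
            rows.append({
                "sample_id": r["sample_id"],
                "variety": r["variety"],
                "estimate": r["estimate"],
                "declared": ref,
                "abs_error": abs(r["estimate"] - ref),
            })
        return pd.DataFrame(rows)


def screen_samples(
    results: dict,
    unknowns: SpectraSet,
    calibration_min: float = 1.0,
    region: tuple | None = None,
) -> ScreeningReport:
    """Apply each variety's chosen models to unknown spectra.

    ``results`` maps variety name to :class:`VarietyResult` (or any object
    with ``qualitative``/``quantitative`` selection reports).  Quantitative
    estimates are produced only for qualitatively positive calls.
    """
    if region is not None:
        unknowns = cut_region(unknowns, *region)
    rows = []
    for variety, res in results.items():
        q_entry = res.qualitative.chosen_entry
        r_entry = res.quantitative.chosen_entry
        sq = q_entry.pretreatment.transform(unknowns)
        flags = np.asarray(q_entry.model.predict(sq.absorbance)).astype(bool)
        sr = r_entry.pretreatment.transform(unknowns)
        est_all = np.asarray(r_entry.model.predict(sr.absorbance), dtype=float)
        for i, sid in enumerate(unknowns.sample_ids):
            positive = bool(flags[i])
            est = float(est_all[i]) if positive else math.nan
            rows.append({
                "sample_id": sid,
                "variety": variety,
                "positive": positive,
                "estimate": est,
                "below_calibration": positive and est < calibration_min,
                "display": format_screening_value(
                    positive, est if positive else None, calibration_min
                ),
            })
    return ScreeningReport(pd.DataFrame(rows), calibration_min)


# ----------------------------------------------------------------------
# full experiment

@dataclass(eq=False)
class ExperimentResult:
    """Bundle returned by :func:`run_full_experiment`."""

    generator: GeneratorConfig
    workflow: WorkflowConfig
    design: MixtureDesign
    spectra: SpectraSet
    composition: CompositionTable
    results: dict              # variety -> VarietyResult
    commercial_design: MixtureDesign
    screening: ScreeningReport
    manifest: dict

    def qualitative_summary(self) -> pd.DataFrame:
        rows = []
        for v, r in self.results.items():
            row = r.qualitative.table.set_index("pretreatment").loc[
                r.qualitative.chosen
            ]
            rows.append({"variety": v, "pretreatment": r.qualitative.chosen,
                         **row.to_dict(),
                         "lod": r.lod.label if r.lod else ""})
        return pd.DataFrame(rows)

    def quantitative_summary(self) -> pd.DataFrame:
        rows = []
        for v, r in self.results.items():
            row = r.quantitative.table.set_index("pretreatment").loc[
                r.quantitative.chosen
            ]
            rows.append({"variety": v, "pretreatment": r.quantitative.chosen,
                         **row.to_dict()})
        return pd.DataFrame(rows)


def _config_manifest(gen: GeneratorConfig, wf: WorkflowConfig,
                     n_commercial: int) -> dict:
    cfg = {
        "generator": gen.to_dict(),
        "workflow": {**asdict(wf), "lod_levels": list(wf.lod_levels),
                     "region": list(wf.region) if wf.region else None},
        "n_commercial": n_commercial,
    }
    blob = json.dumps(cfg, sort_keys=True)
    return {
        "seed": gen.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "version": __version__,
    }


def run_full_experiment(
    gen_config: GeneratorConfig,
    wf_config: WorkflowConfig | None = None,
    out_dir=None,
    n_commercial: int = 5,
    varieties_to_model: tuple | None = None,
) -> ExperimentResult:
    """Simulate the complete study and run every stage.

    Generates the 87-row calibration design (63 equal-proportion subsets +
    24 triturations), runs the qualitative and quantitative workflow for
    each variety (or for ``varieties_to_model``), screens a set of
    commercial-like unknown blends, and optionally writes all reports plus a
    run manifest under ``out_dir``.  Identical configs and seed reproduce
    every output byte-identically.
    """
    wf = wf_config or WorkflowConfig(seed=gen_config.seed)
    endmembers = generate_endmembers(gen_config)
    varieties = endmembers.variety_names
    design = build_full_design(varieties, wf.lod_levels)
    spectra, composition = synthesize_spectra(design, endmembers, gen_config,
                                              stream=1)
    region = wf.region
    if region is None and gen_config.mode == "MIDIR":
        region = (650.0, 2000.0)
        wf = WorkflowConfig(**{**asdict(wf), "region": region})

    model_set = varieties_to_model or varieties
    results = {}
    for i, v in enumerate(model_set):
        cfg_v = WorkflowConfig(**{**asdict(wf), "seed": wf.seed + 10 * i})
        results[v] = run_variety_workflow(
            spectra, composition, v, cfg_v, design.labels
        )

    commercial = build_commercial_design(varieties, n_commercial, gen_config.seed)
    comm_spectra, _ = synthesize_spectra(commercial, endmembers, gen_config,
                                         stream=2)
    screening = screen_samples(results, comm_spectra, wf.calibration_min, region)
    manifest = _config_manifest(gen_config, wf, n_commercial)

    result = ExperimentResult(
        gen_config, wf, design, spectra, composition, results,
        commercial, screening, manifest,
    )
    if out_dir is not None:
        write_experiment_reports(result, out_dir)
    return result


def write_experiment_reports(result: ExperimentResult, out_dir) -> None:
    """Write all CSV reports and the manifest (deterministic bytes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spectra_csv(result.spectra, out / "spectra.csv")
    write_composition_csv(result.composition, out / "composition.csv")
    write_composition_csv(result.commercial_design.composition,
                          out / "commercial_composition.csv")
    qual_rows, quant_rows, lod_rows = [], [], []
    for v, r in result.results.items():
        for _, row in r.qualitative.table.iterrows():
            qual_rows.append({"variety": v, **row.to_dict(),
                              "chosen": row["pretreatment"] == r.qualitative.chosen})
        for _, row in r.quantitative.table.iterrows():
            quant_rows.append({"variety": v, **row.to_dict(),
                               "chosen": row["pretreatment"] == r.quantitative.chosen})
        if r.lod is not None:
            lod_rows.append({
                "variety": v,
                "levels": ";".join(f"{x:g}" for x in r.lod.levels_tested),
                "flags": ";".join("+" if f else "-" for f in r.lod.positive_flags),
                "lod": r.lod.label,
            })
    pd.DataFrame(qual_rows).to_csv(out / "qualitative_report.csv", index=False)
    pd.DataFrame(quant_rows).to_csv(out / "quantitative_report.csv", index=False)
    pd.DataFrame(lod_rows).to_csv(out / "lod_report.csv", index=False)
    result.screening.table.to_csv(out / "screening.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, sort_keys=True, indent=2), encoding="utf-8"
    )
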