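"""End-to-end pipeline: simulate/load -> preprocess -> occurrence -> PCA ->
forest + SMD -> relation map -> report.

The pipeline is driven by a flat key/value configuration (``key = value``
per line, ``#`` comments) and a single integer seed; identical
``(config, seed)`` pairs produce byte-identical CSV outputs.  Every stage
writes its artifacts into the run directory before the next stage starts,
so a failing stage preserves all upstream outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import band_occurrence as bo
from . import forest_smd as fs
from . import preprocessing as pp
from . import reporting
from . import synthetic
from .errors import ConfigError, PipelineError, SelectionError
from .spectra_io import SpectraSet, read_spectra, write_spectra

__all__ = ["PipelineConfig", "load_config", "save_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.12g"


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; every field maps to one config-file key."""

    # synthetic data (ignored when dataset_csv is given)
    n_per_class: int = 400
    n_reference: int = 200
    noise_sd: float = 1.0
    spike_rate: float = 0.05
    amplitude_cv: float = 0.3
    # optional external inputs
    dataset_csv: str = ""
    reference_csv: str = ""
    # preprocessing
    signal_snr_min: float = 5.0
    asls_lambda: float = 1e5
    asls_p: float = 0.01
    # band occurrence
    grid_step: float = 5.0
    grid_half_width: float = 10.0
    k_sigma: float = 3.0
    # PCA
    pca_components: int = 5
    # forest / SMD
    num_trees: int = 1000
    min_node_size: int = 5
    train_fraction: float = 0.8
    n_null: int = 5
    representative_gap: int = 2
    # relation map
    top_q: float = 0.95
    make_figures: bool = True


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` configuration file."""
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    values = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = (s.strip() for s in line.partition("="))
        if key not in fields:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        typ = fields[key].type
        if typ == "bool":
            values[key] = val.lower() in {"1", "true", "yes"}
        elif typ == "int":
            values[key] = int(val)
        elif typ == "float":
            values[key] = float(val)
        else:
            values[key] = val
    return PipelineConfig(**values)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"{f.name} = {getattr(config, f.name)}"
        for f in dataclasses.fields(PipelineConfig)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def _stage(name: str, log_lines: list):
    """Decorator-free stage guard: returns a context manager."""

    class _Guard:
        def __enter__(self):
            log_lines.append(f"stage={name} status=start")
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log_lines.append(f"stage={name} status=error detail={exc}")
                raise PipelineError(name, str(exc)) from exc
            log_lines.append(f"stage={name} status=done")
            return False

    return _Guard()


def run_pipeline(
    config: PipelineConfig, seed: int, out_dir: str | Path
) -> Path:
    """Execute the full analysis chain and write all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list = [f"seed={seed}"]
    rng = np.random.default_rng(seed)
    seeds = {
        name: int(rng.integers(0, 2**31 - 1))
        for name in ("dataset", "reference", "split", "forest", "threshold")
    }
    save_config(config, out / "config_resolved.txt")
    (out / "seed.txt").write_text(f"{seed}\n")

    def _flush_log():
        (out / "run.log").write_text("\n".join(log_lines) + "\n")

    try:
        # ---------------------------------------------------------- simulate
        with _stage("simulate", log_lines):
            if config.dataset_csv:
                dataset = read_spectra(config.dataset_csv)
                reference = read_spectra(config.reference_csv)
            else:
                gen = synthetic.default_config(config.n_per_class)
                gen.noise_sd = config.noise_sd
                gen.spike_rate = config.spike_rate
                gen.amplitude_cv = config.amplitude_cv
                dataset, truth = synthetic.generate_dataset(gen, seeds["dataset"])
                reference = synthetic.generate_signal_free(
                    gen, config.n_reference, seeds["reference"]
                )
                pd.DataFrame(
                    truth, columns=[f"band_{b.center:.0f}" for b in gen.bands]
                ).to_csv(out / "occurrence_truth.csv", index=False)
            write_spectra(dataset, out / "dataset.csv")
            write_spectra(reference, out / "reference.csv")
            log_lines.append(f"stage=simulate n={dataset.n} p={dataset.p}")

        # -------------------------------------------------------- preprocess
        with _stage("preprocess", log_lines):
            ppcfg = pp.PreprocessConfig(
                signal_snr_min=config.signal_snr_min,
                asls_lambda=config.asls_lambda,
                asls_p=config.asls_p,
            )
            clean, rejected = pp.preprocess_set(dataset, ppcfg)
            for idx, reason in rejected:
                log_lines.append(f"stage=preprocess rejected_row={idx} reason={reason}")
            ref_clean, _ = pp.preprocess_set(reference, ppcfg, apply_signal_filter=False)
            write_spectra(clean, out / "preprocessed.csv")
            write_spectra(ref_clean, out / "reference_preprocessed.csv")
            log_lines.append(
                f"stage=preprocess kept={clean.n} rejected={len(rejected)}"
            )

        # -------------------------------------------------------- occurrence
        with _stage("occurrence", log_lines):
            centers = np.arange(
                clean.axis.centers[0],
                clean.axis.centers[-1] + config.grid_step / 2,
                config.grid_step,
            )
            grid = bo.OccurrenceGrid(centers, config.grid_half_width)
            ref_int = bo.build_reference(ref_clean, grid)
            histograms, averages = {}, {}
            for cond in sorted(set(clean.labels)):
                sub = clean.subset(clean.labels == cond)
                hist = bo.occurrence_histogram(sub, grid, ref_int, config.k_sigma)
                histograms[cond] = hist
                averages[cond] = reporting.average_spectrum(clean, cond)
                pd.DataFrame(
                    {
                        "center_cm1": grid.centers,
                        "count": hist.counts,
                        "relative": hist.relative,
                    }
                ).to_csv(
                    out / f"occurrence_{cond}.csv", index=False,
                    float_format=_FLOAT_FORMAT,
                )
            if config.make_figures:
                reporting.plot_occurrence_panels(
                    averages, histograms, out / "occurrence_panels.png"
                )

        # --------------------------------------------------------------- pca
        with _stage("pca", log_lines):
            k = min(config.pca_components, clean.n - 1)
            pca = reporting.run_pca(clean, k)
            frame = pd.DataFrame(
                pca.scores, columns=[f"pc{i + 1}" for i in range(k)]
            )
            frame.insert(0, "label", clean.labels)
            frame.to_csv(out / "pca_scores.csv", index=False, float_format=_FLOAT_FORMAT)
            pd.DataFrame(
                {"component": np.arange(1, k + 1),
                 "explained_variance": pca.explained_variance}
            ).to_csv(out / "pca_variance.csv", index=False, float_format=_FLOAT_FORMAT)

        # ------------------------------------------------------------ rf-smd
        with _stage("rf-smd", log_lines):
            params = fs.ForestParams(
                num_trees=config.num_trees,
                min_node_size=config.min_node_size,
                train_fraction=config.train_fraction,
                seed=seeds["forest"],
            )
            train, test = fs.split_train_test(
                clean, config.train_fraction, seeds["split"]
            )
            forest = fs.fit_forest(train, params, surrogates=True)
            test_eval = fs.evaluate(forest, test)
            train_eval = fs.evaluate(forest, train)
            oob = fs.oob_predictions(forest, train)
            covered = np.array([o is not None for o in oob])
            oob_acc = (
                float((oob[covered] == train.labels[covered]).mean())
                if covered.any()
                else float("nan")
            )
            acc_rows = [
                {"metric": "test_accuracy", "value": test_eval.accuracy},
                {"metric": "train_accuracy", "value": train_eval.accuracy},
                {"metric": "oob_accuracy", "value": oob_acc},
            ]
            acc_rows += [
                {"metric": f"test_sensitivity_{cls}", "value": val}
                for cls, val in sorted(test_eval.sensitivity.items())
            ]
            pd.DataFrame(acc_rows).to_csv(
                out / "accuracy.csv", index=False, float_format=_FLOAT_FORMAT
            )
            smd = fs.surrogate_minimal_depth(forest)
            threshold = fs.smd_threshold(
                train, params, config.n_null, seeds["threshold"]
            )
            result = fs.SMDResult.from_threshold(smd, threshold)
            pd.DataFrame(
                {
                    "variable": np.arange(clean.p),
                    "wavenumber_cm1": clean.axis.centers,
                    "smd": result.smd,
                    "selected": result.selected.astype(int),
                }
            ).to_csv(out / "smd.csv", index=False, float_format=_FLOAT_FORMAT)
            log_lines.append(
                f"stage=rf-smd test_accuracy={test_eval.accuracy:.4f} "
                f"threshold={threshold:.4f} selected={int(result.selected.sum())}"
            )

        # ------------------------------------------------------------ relate
        with _stage("relate", log_lines):
            table = reporting.load_band_assignments()
            try:
                reps = fs.pick_representatives(
                    result.selected, result.smd, clean.axis, config.representative_gap
                )
            except SelectionError:
                reps = []
                log_lines.append("stage=relate note=empty-selection")
            if reps:
                rel = fs.maa_matrix(forest, reps)
                maa_frame = pd.DataFrame(
                    rel.maa,
                    index=[f"{clean.axis.centers[r]:.1f}" for r in reps],
                    columns=[f"{c:.1f}" for c in clean.axis.centers],
                )
                maa_frame.to_csv(out / "maa.csv", float_format=_FLOAT_FORMAT)
                relations = reporting.build_relation_map(
                    rel, clean.axis, table, config.top_q
                )
                relations.to_csv(
                    out / "relations.csv", index=False, float_format=_FLOAT_FORMAT
                )
                if config.make_figures:
                    reporting.plot_relation_heatmap(
                        rel, clean.axis, table, out / "relation_heatmap.png"
                    )
            else:
                (out / "relations.csv").write_text(
                    "representative_cm1,representative_class,"
                    "partner_cm1,partner_class,maa\n"
                )
    finally:
        _flush_log()
    return out
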