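"""End-to-end orchestration: data -> smoothing -> PCA -> SWLDA -> MLP -> report.

A run takes a resolved :class:`~eigenstep.config.PipelineConfig` plus a data
source (a manifest on disk, a synthetic spec, or an in-memory image set),
cross-validates the full pipeline, then fits a final deployable model on
all data and writes every artifact — resolved config, config hash, report,
selection trace, training history, eigenmodel and network weights — under
one self-describing run directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

from .config import PipelineConfig
from .datatypes import LabeledImageSet, Manifest, ValidationError
from .eigen import explained_variance, fit_eigenmodel, project, save_eigenmodel
from .evaluate import ConfusionReport, _prepare, _select_features, cross_validate, make_folds
from .mlp import save_mlp
from .mlp import train as mlp_train
from .preprocess import load_dataset
from .synth import SynthSpec, generate_dataset

logger = logging.getLogger(__name__)


def resolve_dataset(
    config: PipelineConfig,
    source: Manifest | SynthSpec | LabeledImageSet | str | Path | None = None,
) -> LabeledImageSet:
    """Materialize the input images from whichever source is given.

    Falls back to ``config.synth`` when ``source`` is None; manifests are
    loaded at the configured target size.
    """
    if source is None:
        if config.synth is None:
            raise ValidationError("no data source: pass one or set config.synth")
        source = config.synth
    if isinstance(source, LabeledImageSet):
        return source
    if isinstance(source, SynthSpec):
        return generate_dataset(source)
    return load_dataset(
        source, config.preprocess.height, config.preprocess.width
    )


def run_pipeline(
    config: PipelineConfig,
    source: Manifest | SynthSpec | LabeledImageSet | str | Path | None = None,
    out_dir: str | Path | None = None,
) -> ConfusionReport:
    """Cross-validate the pipeline and persist a full run directory.

    Returns the cross-validation report.  When ``out_dir`` is given, the
    directory afterwards contains ``config.yaml``, ``run.json`` (hash,
    stage dimensions, timings), ``report.json``/``report.txt``/
    ``per_class.csv``, ``selection.json``, ``history.json``, and the
    serialized eigenmodel and network of a final fit on all the data.
    """
    t0 = time.perf_counter()
    dataset = resolve_dataset(config, source)
    if len(dataset) == 0:
        raise ValidationError("empty dataset")
    logger.info("dataset: %d images of %s, %d classes",
                len(dataset), dataset.image_shape, dataset.n_classes)
    if config.preprocess.filter_size is None:
        logger.info("averaging filter disabled by configuration")

    plan = make_folds(dataset.labels, config.eval.n_folds, config.eval.seed)
    t1 = time.perf_counter()
    report = cross_validate(dataset, config, plan)
    t2 = time.perf_counter()

    # final fit on all data: the deployable model
    smoothed = _prepare(dataset, config)
    flat = smoothed.flatten()
    k_eff = min(config.pca_k, len(dataset) - 1, flat.shape[1])
    eigenmodel = fit_eigenmodel(flat, k_eff)
    scores = project(eigenmodel, flat)
    selected, selection = _select_features(
        scores.scores, dataset.labels, dataset.n_classes, config.stepwise
    )
    mlp_config = replace(
        config.mlp,
        input_dim=len(selected),
        output_dim=dataset.n_classes,
        seed=config.eval.seed,
    )
    net, history = mlp_train(scores.scores[:, selected], dataset.labels, mlp_config)
    t3 = time.perf_counter()
    fractions, cumulative = explained_variance(eigenmodel)
    logger.info(
        "final fit: K=%d components (%.1f%% variance), %d features selected",
        k_eff, 100 * cumulative[-1], len(selected),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        (out_dir / "report.txt").write_text(report.to_text() + "\n")
        (out_dir / "per_class.csv").write_text(report.per_class_csv())
        (out_dir / "selection.json").write_text(
            json.dumps(
                {"selected": [int(f) for f in selected],
                 "stepwise": selection.to_dict()},
                indent=2,
            )
        )
        (out_dir / "history.json").write_text(
            json.dumps(history.__dict__, indent=2)
        )
        save_eigenmodel(eigenmodel, out_dir / "eigenmodel")
        save_mlp(net, out_dir / "mlp")
        run_meta = {
            "config_hash": config.config_hash(),
            "n_images": len(dataset),
            "image_shape": list(dataset.image_shape),
            "n_classes": dataset.n_classes,
            "pca_components": int(k_eff),
            "explained_variance_cumulative": float(cumulative[-1]),
            "n_selected_features": len(selected),
            "timings_sec": {
                "data": round(t1 - t0, 3),
                "cross_validation": round(t2 - t1, 3),
                "final_fit": round(t3 - t2, 3),
            },
        }
        (out_dir / "run.json").write_text(json.dumps(run_meta, indent=2))
    return report
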