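"""Benchmark harness: proposed model vs bicubic on synthetic datasets.

Produces a report with one row per (model, dataset, scale), each row
carrying Params [K], Runtime [ms] (informational — hardware dependent),
and PSNR/SSIM.  The text rendering fuses PSNR/SSIM into one cell
(PSNR to 2 decimals, SSIM to 4) in the conventional comparison-table
style; the CSV keeps exact separate columns for machine use.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

from .data import DegradationSpec, PhantomSpec, make_dataset
from .errors import ContractError
from .model import ModelConfig, build_model
from .train import BicubicBaseline, TrainOptions, evaluate, train


@dataclass
class MetricReport:
    """Rows of benchmark results."""

    rows: list[dict] = field(default_factory=list)

    def add(self, scale: int, dataset: str, row: dict) -> None:
        self.rows.append({"scale": scale, "dataset": dataset, **row})


def render_report(report: MetricReport) -> tuple[str, str]:
    """Return (text table, CSV).  Deterministic column order; the CSV
    round-trips numerically."""
    if not report.rows:
        raise ContractError("empty report")
    datasets = sorted({r["dataset"] for r in report.rows})
    header = ["Scale", "Model", "Params [K]", "Runtime [ms]"] + [
        f"{d} PSNR/SSIM" for d in datasets
    ]
    # group rows by (scale, model)
    table: dict[tuple[int, str], dict] = {}
    for r in report.rows:
        key = (r["scale"], r["model"])
        entry = table.setdefault(
            key, {"params_k": r["params_k"], "runtime_ms": r["runtime_ms"], "cells": {}}
        )
        entry["cells"][r["dataset"]] = f"{r['psnr_db']:.2f}/{r['ssim']:.4f}"
    lines = ["\t".join(header)]
    for (scale, model_name), entry in sorted(table.items()):
        cells = [entry["cells"].get(d, "-") for d in datasets]
        lines.append(
            "\t".join(
                [
                    f"{scale}x",
                    model_name,
                    str(entry["params_k"]),
                    f"{entry['runtime_ms']:.2f}",
                ]
                + cells
            )
        )
    text = "\n".join(lines) + "\n"

    buf = io.StringIO()
    writer = csv.DictWriter(
        buf,
        fieldnames=[
            "scale", "dataset", "model", "params", "params_k",
            "runtime_ms", "psnr_db", "ssim", "n_images",
        ],
    )
    writer.writeheader()
    for r in report.rows:
        writer.writerow({k: r.get(k) for k in writer.fieldnames})
    return text, buf.getvalue()


def run_benchmark(
    scales: tuple[int, ...] = (2, 4),
    modalities: tuple[str, ...] = ("ct_mri_like", "ultrasound_like"),
    n_images: int = 10,
    phantom_size: int | None = None,
    model_config: ModelConfig | None = None,
    train_opts: TrainOptions | None = None,
    seed: int = 0,
) -> MetricReport:
    """Train and evaluate the proposed model and the bicubic baseline on
    each (modality, scale) synthetic dataset."""
    report = MetricReport()
    base_cfg = model_config or ModelConfig()
    base_opts = train_opts or TrainOptions()
    for modality in modalities:
        for scale in scales:
            dataset = make_dataset(
                n_images,
                PhantomSpec(modality=modality, size=phantom_size, seed=seed),
                DegradationSpec(scale=scale, seed=seed + 10_000),
            )
            from dataclasses import replace

            cfg = replace(base_cfg, scale=scale, seed=seed)
            model = build_model(cfg)
            model, _ = train(model, dataset, base_opts)
            report.add(scale, modality, evaluate(model, dataset, name="ours"))
            report.add(
                scale,
                modality,
                evaluate(BicubicBaseline(scale), dataset, name="bicubic"),
            )
    return report
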