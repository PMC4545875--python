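"""End-to-end orchestration: cohort -> connectivity -> hubs -> statistics.

``run_pipeline`` takes a single ``RunConfig``, obtains a cohort (either
simulated or read from a directory of EDF files), runs the per-subject
analysis chain — common average reference, band filtering, instantaneous
phase, PLI matrix, regional PLI, maximum-weight spanning tree,
betweenness centrality, center of mass — and produces a tidy cohort
table, a summary report with trend statistics, optional head-map
figures, and a plain-text log that records every convention the
analysis depends on (channel count, BC normalization, regional
averaging convention, Bonferroni factor, seed).  Given the same config
and seed the outputs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .montage import Montage, standard_montage, REGION_NAMES
from .preprocessing import (
    DEFAULT_BANDS,
    PhaseEpochs,
    band_by_name,
    bandpass,
    common_average_reference,
    instantaneous_phase,
)
from .connectivity import pli_matrix, regional_pli
from .mst import build_mst, betweenness, regional_bc
from .topography import center_of_mass, render_headmap
from .recording import EpochedRecording, GROUP_NAMES
from .simulate import SimulationSpec, iter_cohort
from .stats import regional_amplitude, results_summary

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "epoch_stability_report"]


@dataclass
class RunConfig:
    """Everything that determines a pipeline run.

    Defaults are the analysis conventions used throughout the package:
    the 19-channel analytic set, BC normalized by N(N-1)/2, regional PLI
    over within-region pairs, Bonferroni factor 4.
    """

    mode: str = "simulate"  # "simulate" | "edf_dir"
    spec: SimulationSpec = field(default_factory=SimulationSpec)
    data_dir: str | None = None
    bands: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)
    include_unclustered: bool = False
    bc_denominator: str = "pairs"
    regional_convention: str = "within"
    correction_factor: float = 4.0
    outdir: str = "hubshift_run"
    seed: int = 0
    make_figures: bool = False
    save_intermediates: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "edf_dir"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "edf_dir" and not self.data_dir:
            raise ValueError("edf_dir mode needs data_dir")

    def to_json(self) -> str:
        d = asdict(self)
        d["spec"] = json.loads(self.spec.to_json()) if self.spec else None
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if d.get("spec") is not None:
            d["spec"] = SimulationSpec.from_json(json.dumps(d["spec"]))
        d["bands"] = tuple(d["bands"])
        return cls(**d)


@dataclass
class PipelineResult:
    cohort_table: pd.DataFrame
    summary: pd.DataFrame
    outdir: Path


def _iter_recordings(config: RunConfig, montage: Montage):
    if config.mode == "simulate":
        spec = config.spec
        if config.seed != spec.seed:
            spec = SimulationSpec.from_json(spec.to_json())
            spec.seed = config.seed
        yield from iter_cohort(spec, montage)
    else:
        from .edf import read_edf

        paths = sorted(Path(config.data_dir).glob("*.edf"))
        if not paths:
            raise ValueError(f"no EDF files under {config.data_dir}")
        for p in paths:
            yield read_edf(p, montage)


def analyze_subject(
    recording: EpochedRecording,
    montage: Montage,
    bands: tuple[str, ...],
    bc_denominator: str = "pairs",
    regional_convention: str = "within",
) -> tuple[list[dict], dict]:
    """Run the per-subject analysis chain; returns tidy rows and the
    per-band intermediates (matrix, tree, bc, com)."""
    referenced = common_average_reference(recording.data)
    amplitude = regional_amplitude(recording, montage)
    rows: list[dict] = []
    intermediates: dict = {}
    for band_name in bands:
        band = band_by_name(band_name)
        filtered = bandpass(referenced, band, recording.sampling_rate)
        phases = instantaneous_phase(filtered, band)
        matrix = pli_matrix(phases)
        reg_pli = regional_pli(matrix, montage, convention=regional_convention)
        tree = build_mst(matrix)
        cv = betweenness(tree, denominator=bc_denominator)
        reg_bc = regional_bc(cv, montage)
        com = center_of_mass(cv, montage)
        intermediates[band_name] = {
            "matrix": matrix,
            "tree": tree,
            "bc": cv,
            "com": com,
        }
        for region in list(REGION_NAMES) + ["global"]:
            rows.append(
                {
                    "subject_id": recording.subject_id,
                    "group": recording.group,
                    "group_name": GROUP_NAMES[recording.group],
                    "sex": recording.sex,
                    "mmse": recording.mmse,
                    "band": band_name,
                    "region": region,
                    "pli": reg_pli.values[region],
                    "bc": reg_bc[region],
                    "com_x": com.x,
                    "com_y": com.y,
                    "amplitude": amplitude[region],
                }
            )
    return rows, intermediates


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write its result bundle under
    ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    montage = standard_montage(include_unclustered=config.include_unclustered)
    montage.to_csv(outdir / "montage.csv")
    (outdir / "config.json").write_text(config.to_json())

    rows: list[dict] = []
    bc_sums: dict[str, np.ndarray] = {}
    bc_counts: dict[tuple[str, int], int] = {}
    bc_group_sums: dict[tuple[str, int], np.ndarray] = {}
    inter_dir = outdir / "intermediates"
    n_subjects = 0
    for recording in _iter_recordings(config, montage):
        n_subjects += 1
        try:
            sub_rows, inter = analyze_subject(
                recording,
                montage,
                config.bands,
                config.bc_denominator,
                config.regional_convention,
            )
        except Exception as exc:
            raise RuntimeError(
                f"analysis failed for subject {recording.subject_id}: {exc}"
            ) from exc
        rows.extend(sub_rows)
        for band_name, parts in inter.items():
            key = (band_name, recording.group)
            bc_group_sums[key] = (
                bc_group_sums.get(key, 0.0) + parts["bc"].bc
            )
            bc_counts[key] = bc_counts.get(key, 0) + 1
            if config.save_intermediates:
                sdir = inter_dir / recording.subject_id
                sdir.mkdir(parents=True, exist_ok=True)
                parts["matrix"].to_csv(sdir / f"pli_{band_name}.csv", montage)
                parts["tree"].to_frame(montage).to_csv(
                    sdir / f"mst_{band_name}.csv", index=False
                )
                pd.DataFrame(
                    {
                        "channel": list(montage.channels),
                        "bc": parts["bc"].bc,
                    }
                ).to_csv(sdir / f"bc_{band_name}.csv", index=False)

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "cohort_table.csv", index=False)
    summary = results_summary(table, correction_factor=config.correction_factor)
    summary.to_csv(outdir / "summary.csv", index=False)

    if config.make_figures:
        for (band_name, group), total in bc_group_sums.items():
            mean_bc = total / bc_counts[(band_name, group)]
            com = center_of_mass(mean_bc, montage)
            render_headmap(
                mean_bc,
                montage,
                outdir / f"headmap_{band_name}_{GROUP_NAMES[group]}.png",
                mass_center=com,
                title=f"{band_name} / {GROUP_NAMES[group]}",
            )

    log_lines = [
        f"hubshift version: {__version__}",
        f"mode: {config.mode}",
        f"seed: {config.seed}",
        f"subjects: {n_subjects}",
        f"bands: {', '.join(config.bands)}",
        f"channel count: {montage.n_channels}",
        f"bc normalization: {config.bc_denominator}",
        f"regional PLI convention: {config.regional_convention}",
        f"bonferroni factor: {config.correction_factor}",
    ]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(cohort_table=table, summary=summary, outdir=outdir)


def epoch_stability_report(
    spec: SimulationSpec | None = None,
    epochs_list: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8),
    n_subjects: int = 50,
    seed: int = 0,
    band: str = "lower_alpha",
    montage: Montage | None = None,
) -> pd.DataFrame:
    """Mean |global PLI(k epochs) - global PLI(max epochs)| per k.

    Simulates ``n_subjects`` recordings with the maximum epoch count in
    ``epochs_list``, computes the epoch-averaged global mean PLI from
    the first k epochs for every k, and reports the mean absolute
    deviation from the max-epoch value across subjects.
    """
    if montage is None:
        montage = standard_montage()
    if spec is None:
        spec = SimulationSpec(bands=(band,))
    k_max = max(epochs_list)
    sim_spec = SimulationSpec.from_json(spec.to_json())
    sim_spec.n_epochs = k_max
    sim_spec.seed = seed
    band_def = band_by_name(band)
    n = montage.n_channels
    iu = np.triu_indices(n, k=1)
    deltas = {k: [] for k in epochs_list}
    from .simulate import simulate_subject, subject_rng

    for s in range(n_subjects):
        rec = simulate_subject(
            sim_spec, 0, montage, subject_rng(seed, 0, s), f"sub-{s:03d}"
        )
        data = common_average_reference(rec.data)
        data = bandpass(data, band_def, rec.sampling_rate)
        phases = instantaneous_phase(data, band_def).phases
        per_epoch = np.stack(
            [
                pli_matrix(PhaseEpochs(band=band_def, phases=phases[[ep]])).values
                for ep in range(k_max)
            ]
        )
        global_k = {
            k: per_epoch[:k].mean(axis=0)[iu].mean() for k in epochs_list
        }
        ref = per_epoch[:k_max].mean(axis=0)[iu].mean()
        for k in epochs_list:
            deltas[k].append(abs(global_k[k] - ref))
    return pd.DataFrame(
        {
            "n_epochs": list(epochs_list),
            "mean_abs_delta": [float(np.mean(deltas[k])) for k in epochs_list],
        }
    )
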