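"""End-to-end orchestration: simulate -> select -> sample -> analyze.

A run reproduces the experimental workflow in silico: a molecule population
is deaminated, passed through the denaturation-temperature gradient, clones
are sampled from the lowest positive band (the wet-lab protocol sequences
the band just below the restrictive temperature), and the clone set is
analysed for substitution spectrum, editing context and hypermutant
fraction.  Every run is reproducible bit-for-bit from its config and seed;
all stage seeds are derived from the master seed, never from wall-clock
entropy.

An analysis-only entry point applies the same statistics to user-provided
clone FASTA without any simulation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .editing_sim import (CONTEXTS, EditingModel, MoleculeSet, mutation_load,
                          plus_strand_edit_probabilities, simulate_editing)
from .hypermut_stats import (ContextReport, MutationMatrix,
                             classify_hypermutants, context_report,
                             mutation_matrix, plot_context)
from .target_io import (TargetSequence, generate_target, read_fasta,
                        reverse_complement, write_fasta)
from .thermo_3dpcr import (GradientResult, TmModel, default_gradient,
                           sample_band, simulate_3dpcr)

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_NO_RECOVERY = "no sub-restrictive recovery"

_TD_TOL = 1e-9


@dataclass
class RunConfig:
    """Fully serializable description of a pipeline run.

    The target is either loaded from ``target_path`` (first FASTA record) or
    generated synthetically from ``target_length``/``target_gc``.
    ``sampled_td`` of None means "the lowest positive Td", matching the
    protocol of sequencing the last retrieved band.
    """

    target_path: str | None = None
    target_length: int = 500
    target_gc: float = 0.45

    rate: float = 0.4
    context_weights: dict[str, float] = field(
        default_factory=lambda: {"ApC": 0.1, "CpC": 0.1, "GpC": 0.1, "TpC": 0.7})
    strand_policy: str = "both_random"
    substrate: str = "dC"
    error_rate: float = 0.0

    restrictive_td: float = 85.7
    delta_per_sub: float = 0.04
    epsilon: float = 0.0
    gradient_steps: int = 12
    gradient_span_below: float = 5.0
    gradient_span_above: float = 4.0
    min_templates: int = 1

    n_molecules: int = 1000
    n_clones: int = 20
    sampled_td: float | None = None
    background_rate: float = 1e-4

    seed: int = 0

    def editing_model(self) -> EditingModel:
        return EditingModel(rate=self.rate, context_weights=dict(self.context_weights),
                            strand_policy=self.strand_policy,
                            substrate=self.substrate, error_rate=self.error_rate)

    def tm_model(self) -> TmModel:
        return TmModel(restrictive_td=self.restrictive_td,
                       delta_per_sub=self.delta_per_sub, epsilon=self.epsilon)

    def gradient(self) -> list[float]:
        return default_gradient(self.restrictive_td, self.gradient_steps,
                                self.gradient_span_below, self.gradient_span_above)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Aggregated result of a pipeline or analysis run."""

    status: str
    last_positive_td: float | None
    recovery_table: pd.DataFrame | None
    sampled_td: float | None
    clone_ids: list[str] | None
    matrix: MutationMatrix | None
    context: ContextReport | None
    hypermutant_fraction: float | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "last_positive_td": (None if self.last_positive_td is None
                                 else round(self.last_positive_td, 1)),
            "recovery": (None if self.recovery_table is None
                         else self.recovery_table.to_dict(orient="records")),
            "sampled_td": (None if self.sampled_td is None
                           else round(self.sampled_td, 1)),
            "clone_ids": self.clone_ids,
            "mutation_matrix": None if self.matrix is None else self.matrix.to_dict(),
            "context": None if self.context is None else self.context.to_dict(),
            "hypermutant_fraction": self.hypermutant_fraction,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _resolve_target(config: RunConfig, seed: int) -> TargetSequence:
    if config.target_path is not None:
        return read_fasta(config.target_path)[0]
    return generate_target(config.target_length, config.target_gc, seed=seed)


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the full simulate -> gradient -> sample -> analyze run.

    Clones are sampled at ``config.sampled_td`` (default: the lowest
    positive Td).  When no band appears below the restrictive temperature --
    the mock-transfection / dead-enzyme outcome -- the report carries status
    "no sub-restrictive recovery" rather than raising.
    """
    target_seed, edit_seed, sample_seed, _ = _stage_seeds(config.seed)
    target = _resolve_target(config, target_seed)
    ms = simulate_editing(target, config.editing_model(), config.n_molecules,
                          seed=edit_seed)
    gr = simulate_3dpcr(ms, config.gradient(), config.tm_model(),
                        config.min_templates)

    provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                  "version": __version__, "target_id": target.id}

    sampled_td = config.sampled_td
    if sampled_td is None:
        sampled_td = gr.last_positive_td
    status = STATUS_OK
    if (gr.last_positive_td is None
            or gr.last_positive_td >= config.restrictive_td - _TD_TOL):
        status = STATUS_NO_RECOVERY

    matrix = context = None
    clone_ids = None
    hyper_frac = None
    clones: list[str] = []
    if sampled_td is not None:
        clone_ids = sample_band(gr, sampled_td, config.n_clones, seed=sample_seed)
        id_to_mol = dict(zip(ms.ids, ms.molecules))
        clones = [id_to_mol[cid] for cid in clone_ids]
        matrix = mutation_matrix(target, clones)
        context = context_report(target, clones)
        labels = classify_hypermutants(clones, target, config.background_rate)
        hyper_frac = labels.count("hypermutated") / len(labels)

    report = RunReport(status=status, last_positive_td=gr.last_positive_td,
                       recovery_table=gr.to_table(), sampled_td=sampled_td,
                       clone_ids=clone_ids, matrix=matrix, context=context,
                       hypermutant_fraction=hyper_frac, provenance=provenance)

    if outdir is not None:
        _write_artifacts(Path(outdir), config, target, ms, gr, clone_ids,
                         clones, report)
    return report


def _write_artifacts(outdir: Path, config: RunConfig, target: TargetSequence,
                     ms: MoleculeSet, gr: GradientResult,
                     clone_ids: list[str] | None, clones: list[str],
                     report: RunReport) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    write_fasta([target], outdir / "target.fasta")
    ms.to_fasta(outdir / "molecules.fasta")
    ms.edits_to_tsv(outdir / "true_edits.tsv")
    gr.to_table().to_csv(outdir / "gradient.tsv", sep="\t", index=False)
    if clone_ids:
        write_fasta(zip(clone_ids, clones), outdir / "clones.fasta")
    if report.matrix is not None:
        report.matrix.to_tsv(outdir / "mutation_matrix.tsv")
    if report.context is not None:
        report.context.to_json(outdir / "context.json")
        if report.context.n_events > 0:
            plot_context(report.context, outdir / "context.png")
    report.to_json(outdir / "report.json")


def analyze_clones(reference: str | Path | TargetSequence,
                   clones: str | Path | list[str],
                   background_rate: float = 1e-4) -> RunReport:
    """Analysis-only mode: statistics on user-provided clone sequences.

    ``reference`` and ``clones`` may be FASTA paths or in-memory objects.
    All clones must match the reference length (no alignment is attempted);
    offending records are reported by id.
    """
    if not isinstance(reference, TargetSequence):
        reference = read_fasta(reference)[0]
    if isinstance(clones, (str, Path)):
        records = read_fasta(clones)
        bad = [r.id for r in records if len(r.seq) != len(reference)]
        if bad:
            raise ValueError(
                f"clone length != reference length ({len(reference)}) for: "
                + ", ".join(bad))
        clone_seqs = [r.seq for r in records]
        clone_ids = [r.id for r in records]
    else:
        clone_seqs = list(clones)
        clone_ids = [f"clone{i:04d}" for i in range(len(clone_seqs))]

    matrix = mutation_matrix(reference, clone_seqs)
    context = context_report(reference, clone_seqs)
    labels = classify_hypermutants(clone_seqs, reference, background_rate)
    hyper_frac = labels.count("hypermutated") / len(labels) if labels else None
    provenance = {"mode": "analysis-only", "version": __version__,
                  "reference_id": reference.id, "n_clones": len(clone_seqs)}
    return RunReport(status="analysis", last_positive_td=None,
                     recovery_table=None, sampled_td=None,
                     clone_ids=clone_ids, matrix=matrix, context=context,
                     hypermutant_fraction=hyper_frac, provenance=provenance)


def _mean_weighted_sites(target: TargetSequence, model: EditingModel) -> float:
    """Expected edits per molecule at rate=1 under the model's strand policy."""
    probe = EditingModel(rate=1.0, context_weights=model.context_weights,
                         strand_policy=model.strand_policy)
    plus = float(plus_strand_edit_probabilities(target.seq, probe).sum())
    minus = float(plus_strand_edit_probabilities(
        reverse_complement(target.seq), probe).sum())
    if model.strand_policy == "plus_only":
        return plus
    if model.strand_policy == "minus_only":
        return minus
    return (plus + minus) / 2.0


def rate_for_load(target: TargetSequence, model: EditingModel,
                  load_per_kb: float) -> float:
    """Editing rate whose expected mutation load equals ``load_per_kb``."""
    if load_per_kb < 0:
        raise ValueError("load must be non-negative")
    if load_per_kb == 0:
        return 0.0
    mean_edits = load_per_kb * len(target) / 1000.0
    denom = _mean_weighted_sites(target, model)
    if denom == 0:
        raise ValueError(f"{target.id}: no editable sites under this model")
    rate = mean_edits / denom
    if rate > 1.0:
        raise ValueError(
            f"load {load_per_kb}/kb is outside the feasible editing range "
            f"for {target.id} (max {denom / len(target) * 1000:.2f}/kb)")
    return rate


def detection_threshold_scan(config: RunConfig,
                             load_grid: list[float],
                             n_replicates: int = 20) -> float | None:
    """Smallest mutation load (substitutions/kb) that 3DPCR detects.

    For each grid load, populations whose expected mean load equals the grid
    value are simulated over ``n_replicates`` fixed seeds (master seed +
    replicate index); a replicate counts as detected when the last positive
    Td falls strictly below the restrictive temperature.  Returns the
    smallest load detected in at least half the replicates, or None.
    """
    if len(load_grid) < 2 or any(b <= a for a, b in zip(load_grid, load_grid[1:])):
        raise ValueError("load_grid must be ascending with >= 2 points")
    target_seed, _, _, _ = _stage_seeds(config.seed)
    target = _resolve_target(config, target_seed)
    base_model = config.editing_model()
    tm = config.tm_model()
    gradient = config.gradient()

    # validate feasibility up front so an infeasible grid fails fast
    for load in load_grid:
        rate_for_load(target, base_model, load)

    threshold: float | None = None
    for load in sorted(load_grid):
        rate = rate_for_load(target, base_model, load)
        model = EditingModel(rate=rate, context_weights=base_model.context_weights,
                             strand_policy=base_model.strand_policy,
                             substrate=base_model.substrate,
                             error_rate=base_model.error_rate)
        detected = 0
        for rep in range(n_replicates):
            ms = simulate_editing(target, model, config.n_molecules,
                                  seed=config.seed + rep)
            gr = simulate_3dpcr(ms, gradient, tm, config.min_templates)
            if (gr.last_positive_td is not None
                    and gr.last_positive_td < config.restrictive_td - _TD_TOL):
                detected += 1
        logger.info("load %.2f/kb detected in %d/%d replicates",
                    load, detected, n_replicates)
        if detected * 2 >= n_replicates and threshold is None:
            threshold = load
    return threshold
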