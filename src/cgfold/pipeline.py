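"""End-to-end folding runs: select → fragments → fold → cluster → evaluate.

A run is fully described by a RunConfig and a seed; the manifest written
next to the models records everything needed to reproduce it bit-exactly.
The production-scale preset uses 40 replicas, 500 cycles and five
independent simulations; the desk preset runs 8 replicas, 100 cycles and
one simulation, which folds toy fixtures in minutes on one CPU.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import evaluate, formats, fragments, selection
from .forcefield import EnergyModel, Weights, gradient_width
from .formats import ContactMap, SsePrediction
from .geometry import CoarseStructure
from .sampler import DecoySet, SamplerConfig, run_remc
from .selection import RestraintSet


@dataclass
class RunConfig:
    """All knobs of one folding run."""

    preset: str = "desk"          # desk | production
    seed: int = 0
    n_runs: int | None = None     # independent REMC simulations
    nf: float | None = None       # MSA depth; computed from the MSA if given
    weights: Weights = field(default_factory=Weights)
    sampler: SamplerConfig | None = None
    d_b: float | None = None
    fragment_lengths: tuple = fragments.FRAGMENT_LENGTHS
    snapshot_stride: int = 5
    max_decoys_cluster: int = 250
    burn_in_frac: float = 0.3     # trajectory fraction excluded from clustering

    def resolve_sampler(self, L: int) -> SamplerConfig:
        if self.sampler is not None:
            return self.sampler
        if self.preset == "production":
            return SamplerConfig(n_replicas=40, n_cycles=500,
                                 snapshot_stride=self.snapshot_stride)
        return SamplerConfig(n_replicas=8, n_cycles=100,
                             snapshot_stride=self.snapshot_stride)

    def resolve_runs(self) -> int:
        if self.n_runs is not None:
            return self.n_runs
        return 5 if self.preset == "production" else 1


@dataclass
class FoldResult:
    """Outcome of run_fold: ranked models plus diagnostics."""

    models: list[CoarseStructure]
    restraints: RestraintSet
    decoys: list[DecoySet]
    cluster: evaluate.ClusterResult
    report: evaluate.EvalReport | None
    manifest: dict


def _config_hash(cfg: RunConfig, L: int) -> str:
    blob = json.dumps({"preset": cfg.preset, "seed": cfg.seed,
                       "runs": cfg.resolve_runs(), "L": L,
                       "weights": asdict(cfg.weights)},
                      sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_fold(sequence: str, sse: SsePrediction | str,
             contact_maps: list[ContactMap],
             library: list[CoarseStructure],
             config: RunConfig | None = None,
             native: CoarseStructure | None = None,
             msa: list[str] | None = None,
             out_dir=None,
             fragment_library=None,
             profiles=None,
             monitor_restraints: RestraintSet | None = None) -> FoldResult:
    """Run the full contact-guided folding pipeline for one target.

    Contact maps and (optionally) an MSA replace the alignment-building
    and contact-prediction stages of a production pipeline; restraint
    selection, fragment generation, REMC folding, clustering and, when a
    native structure is supplied, evaluation all run in-process.
    Passing a pre-threaded ``fragment_library`` (with its ``profiles``)
    skips the homolog filter and threading stages — useful when many
    runs share one target.  ``monitor_restraints`` lets an unguided run
    log the satisfaction of a reference restraint set along its
    trajectory without feeling any force from it.
    """
    cfg = config or RunConfig()
    L = len(sequence)
    ss_states = sse.states if isinstance(sse, SsePrediction) else sse

    nf = cfg.nf
    if nf is None:
        nf = formats.compute_nf(msa).nf if msa else 1.0

    if contact_maps:
        # depths carry the raw confidence; the energy weight w_con scales
        # the whole term once, inside the force field
        restraints = selection.select_restraints(contact_maps, nf=nf, L=L)
    else:
        restraints = RestraintSet(L, [])
    unguided = len(restraints) == 0

    if fragment_library is not None:
        flib = fragment_library
        profiles = profiles or fragments.build_distance_profiles(flib)
        n_library = len(flib.sources)
    else:
        filtered = fragments.homolog_filter(library, sequence)
        n_library = len(filtered)
        flib = None
        profiles = {}
        if filtered:
            flib = fragments.gapless_thread(sequence, ss_states, filtered,
                                            lengths=cfg.fragment_lengths)
            profiles = fragments.build_distance_profiles(flib)

    model = EnergyModel(sequence, restraints=restraints,
                        profiles=list(profiles.values()),
                        sse=sse if isinstance(sse, SsePrediction) else None,
                        weights=cfg.weights,
                        d_b=cfg.d_b if cfg.d_b is not None else gradient_width(L))

    scfg = cfg.resolve_sampler(L)
    n_runs = cfg.resolve_runs()
    seeds = [int(x) for x in
             np.random.SeedSequence(cfg.seed).generate_state(n_runs) >> 1]
    decoy_sets = [run_remc(sequence, sse, model, flib, scfg, seed=s,
                           monitor_restraints=monitor_restraints)
                  for s in seeds]

    burn_in = int(scfg.n_cycles * cfg.burn_in_frac)
    all_coords, all_energy = [], []
    for dset in decoy_sets:
        keep = [k for k, s in enumerate(dset.snapshots) if s.cycle > burn_in]
        if not keep:
            keep = list(range(len(dset.snapshots)))
        all_coords.append(dset.coords_array()[keep])
        all_energy.append(dset.energies()[keep])
    all_coords = np.concatenate(all_coords)
    all_energy = np.concatenate(all_energy)
    if len(all_coords) > cfg.max_decoys_cluster:
        keep = np.linspace(0, len(all_coords) - 1,
                           cfg.max_decoys_cluster).astype(int)
        all_coords, all_energy = all_coords[keep], all_energy[keep]
    cluster = evaluate.cluster_decoys(all_coords, all_energy)

    models = []
    for rank, cl in enumerate(cluster.clusters[:5], start=1):
        s = CoarseStructure(sequence, all_coords[cl.centroid].copy(),
                            ss=ss_states, name=f"model{rank}")
        models.append(s)

    report = None
    if native is not None and models:
        report = evaluate.evaluate_model(
            models[0], native,
            restraints=restraints if not unguided else None,
            predicted=contact_maps[0] if contact_maps else None)

    manifest = {
        "config_hash": _config_hash(cfg, L),
        "seed": cfg.seed,
        "run_seeds": seeds,
        "preset": cfg.preset,
        "L": L,
        "nf": nf,
        "n_restraints": len(restraints),
        "unguided": unguided,
        "n_decoys": int(len(all_coords)),
        "n_library": n_library,
        "n_profiles": sum(p.usable for p in profiles.values()),
    }

    result = FoldResult(models, restraints, decoy_sets, cluster, report,
                        manifest)
    if out_dir is not None:
        _write_outputs(result, sequence, out_dir)
    return result


def _write_outputs(result: FoldResult, sequence: str, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m in result.models:
        formats.write_structure(m, out / f"{m.name}.pdb")
    if len(result.restraints):
        formats.write_rr(result.restraints.to_contact_map(),
                         out / "selected.rr", sequence)
    with open(out / "trajectory.tsv", "w") as fh:
        fh.write("run\tcycle\tenergy\tsatisfaction\n")
        for run_idx, dset in enumerate(result.decoys):
            for entry in dset.trajectory:
                fh.write(f"{run_idx}\t{entry['cycle']}\t{entry['energy']:.4f}"
                         f"\t{entry.get('satisfaction', float('nan')):.4f}\n")
    manifest = dict(result.manifest)
    if result.report is not None:
        manifest["evaluation"] = result.report.to_dict()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
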