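"""End-to-end orchestration: genotype -> diversity -> divergence -> trees ->
phasing -> clonality, with a machine-readable manifest.

Every stage is a pure function of (inputs, parameters, seed); rerunning a
configuration reproduces byte-identical outputs.  All randomness within a
stage flows through one seeded generator recorded in the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment_io import classify_sites, read_fasta_alignment, write_site_report
from .clonality import (
    from_phased,
    index_of_association,
    phylogenetic_compatibility,
    write_compatibility_report,
    write_ia_report,
)
from .divergence_stats import divergence_report, write_divergence_report
from .errors import ConfigError, MycopopError, PipelineError
from .genotype_diversity import collapse_genotypes, diversity_report, write_diversity_report
from .parsimony import (
    bootstrap_support,
    constrained_search,
    fitch_length,
    ild_test,
    write_newick,
)
from .partition import read_partition
from .phasing import ITS_PARALOGY_WARNING, em_phase, snpify, write_haplotype_fasta, write_phased_tsv


@dataclass
class RunConfig:
    """Pipeline configuration (usually loaded from YAML)."""

    loci: dict[str, str]  # locus name -> FASTA path
    partition: str
    outdir: str
    seed: int
    stages: dict[str, bool] = field(default_factory=dict)
    bootstrap_reps: int = 100
    ild_reps: int = 99
    ia_permutations: int = 999
    constraint_permutations: int = 0
    n_random_addition: int = 5
    phase_max_iter: int = 10_000
    phase_tol: float = 1e-8
    #: population whose strains are phased and association-tested; None
    #: selects the largest population (within-population analysis keeps
    #: sites biallelic — between-lineage sites may carry three states)
    focal_population: str | None = None

    DEFAULT_STAGES = ("genotype", "divergence", "tree", "concordance", "phase", "clonality")

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    def validate(self) -> None:
        if not self.loci:
            raise ConfigError("no loci configured")
        for name, path in self.loci.items():
            if not Path(path).is_file():
                raise ConfigError(f"locus {name!r}: file not found: {path}")
        if not Path(self.partition).is_file():
            raise ConfigError(f"partition file not found: {self.partition}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return RunConfig(
            loci=dict(raw["loci"]),
            partition=str(raw["partition"]),
            outdir=str(raw["outdir"]),
            seed=int(raw["seed"]),
            stages=dict(raw.get("stages", {})),
            bootstrap_reps=int(raw.get("bootstrap_reps", 100)),
            ild_reps=int(raw.get("ild_reps", 99)),
            ia_permutations=int(raw.get("ia_permutations", 999)),
            constraint_permutations=int(raw.get("constraint_permutations", 0)),
            n_random_addition=int(raw.get("n_random_addition", 5)),
            focal_population=raw.get("focal_population"),
        )
    except KeyError as e:
        raise ConfigError(f"missing required config key: {e.args[0]!r}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all enabled stages; returns the manifest dictionary.

    Any stage failure raises :class:`PipelineError` naming the stage; a
    FAILED marker with the stage name is left in the output directory and
    outputs of completed stages are retained.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {"loci": dict(sorted(cfg.loci.items())), "partition": cfg.partition},
        "parameters": {
            "bootstrap_reps": cfg.bootstrap_reps,
            "ild_reps": cfg.ild_reps,
            "ia_permutations": cfg.ia_permutations,
            "constraint_permutations": cfg.constraint_permutations,
            "n_random_addition": cfg.n_random_addition,
        },
        "stages": {},
        "warnings": [],
        "outputs": {},
    }
    stage = "load"
    try:
        loci = {
            name: read_fasta_alignment(path, name) for name, path in sorted(cfg.loci.items())
        }
        partition = read_partition(cfg.partition)
        lineage_groups = [
            frozenset(partition.strains_in_lineage(l)) for l in partition.lineages
        ]

        if cfg.enabled("genotype"):
            stage = "genotype"
            for name, locus in loci.items():
                sc = classify_sites(locus)
                write_site_report(sc, outdir / f"{name}.sites.tsv")
                table = collapse_genotypes(locus, partition)
                results = diversity_report(table)
                write_diversity_report(table, results, outdir / f"{name}.diversity.tsv")
                manifest["stages"].setdefault("genotype", {})[name] = {
                    "n_sites": sc.n_sites,
                    "n_variable": sc.n_variable,
                    "n_substitution": sc.n_substitution,
                    "n_indel_sites": sc.n_indel_sites,
                    "n_indel_tracks": sc.n_indel_tracks,
                    "n_genotypes": table.n_genotypes,
                }

        if cfg.enabled("divergence"):
            stage = "divergence"
            for name, locus in loci.items():
                if len(partition.lineages) >= 2:
                    summaries = divergence_report(locus, partition)
                    write_divergence_report(summaries, outdir / f"{name}.divergence.tsv")
                    manifest["stages"].setdefault("divergence", {})[name] = [
                        {
                            "pair": f"{s.lineage1}-{s.lineage2}",
                            "segregating": s.n_segregating,
                            "fixed": s.n_fixed,
                        }
                        for s in summaries
                    ]

        if cfg.enabled("tree"):
            stage = "tree"
            for name, locus in loci.items():
                if locus.n_strains < 4:
                    continue
                bs = bootstrap_support(
                    locus, n_reps=cfg.bootstrap_reps, seed=cfg.seed,
                    n_random_addition=cfg.n_random_addition,
                )
                write_newick(bs, outdir / f"{name}.tree.nwk")
                score = fitch_length(bs.tree, locus)
                manifest["stages"].setdefault("tree", {})[name] = {
                    "length": score.length,
                    "ci": None if score.length == 0 else round(score.ci, 4),
                    "ri": _maybe(score.ri),
                    "bootstrap_reps": bs.n_reps,
                    "n_variable_sites": bs.n_variable_sites,
                }

        if cfg.enabled("concordance"):
            stage = "concordance"
            multi = [l for l in loci.values() if l.n_strains >= 4]
            shared = None
            if len(multi) >= 2:
                shared = set(multi[0].strain_ids)
                for l in multi[1:]:
                    shared &= set(l.strain_ids)
            concordance: dict = {}
            if shared and len(shared) >= 4:
                common = sorted(shared)
                subset_loci = [l.subset(common) for l in multi]
                variable = [
                    l for l in subset_loci
                    if classify_sites(l).n_substitution > 0
                ]
                if len(variable) >= 2:
                    ild = ild_test(
                        variable, n_reps=cfg.ild_reps, seed=cfg.seed,
                        n_random_addition=cfg.n_random_addition,
                    )
                    concordance["ild"] = {
                        "loci": [l.locus_name for l in variable],
                        "observed": ild.observed,
                        "p_value": round(ild.p_value, 6),
                    }
                for l in variable:
                    res = constrained_search(
                        l,
                        [g & shared for g in lineage_groups],
                        seed=cfg.seed,
                        n_random_addition=cfg.n_random_addition,
                        n_permutations=cfg.constraint_permutations,
                    )
                    concordance.setdefault("constrained", {})[l.locus_name] = {
                        "constrained_length": res.constrained_length,
                        "unconstrained_length": res.unconstrained_length,
                        "delta": res.delta,
                        "p_value": res.p_value,
                    }
            manifest["stages"]["concordance"] = concordance

        phased = {}
        if cfg.enabled("phase"):
            stage = "phase"
            focal = cfg.focal_population
            if focal is None:  # largest population; ties broken by name
                focal = max(
                    partition.populations,
                    key=lambda p: (len(partition.strains_in_population(p)), p),
                )
            focal_strains = set(partition.strains_in_population(focal))
            manifest["stages"]["phase_focal_population"] = focal
            for name, locus in loci.items():
                keep = [s for s in locus.strain_ids if s in focal_strains]
                if len(keep) < 2:
                    continue
                locus = locus.subset(keep)
                try:
                    dm = snpify(locus)
                except MycopopError as e:
                    manifest["warnings"].append(f"phase/{name}: {e}")
                    continue
                if dm.n_sites == 0:
                    manifest["stages"].setdefault("phase", {})[name] = {
                        "n_sites": 0, "n_haplotypes": 1,
                    }
                    continue
                ph = em_phase(dm, max_iter=cfg.phase_max_iter, tol=cfg.phase_tol, seed=cfg.seed)
                if "ITS" in name.upper():
                    ph.warnings.append(ITS_PARALOGY_WARNING)
                    manifest["warnings"].append(f"phase/{name}: {ITS_PARALOGY_WARNING}")
                write_phased_tsv(ph, outdir / f"{name}.phased.tsv")
                write_haplotype_fasta(ph, outdir / f"{name}.haplotypes.fasta")
                phased[name] = ph
                manifest["stages"].setdefault("phase", {})[name] = {
                    "n_sites": dm.n_sites,
                    "n_haplotypes": ph.n_haplotypes,
                    "converged": ph.converged,
                    "method": ph.method,
                }

        if cfg.enabled("clonality") and len(phased) >= 2:
            stage = "clonality"
            matrix = from_phased(phased)
            try:
                ia = index_of_association(
                    matrix, n_permutations=cfg.ia_permutations, seed=cfg.seed
                )
                write_ia_report(ia, outdir / "ia.json")
                manifest["stages"]["clonality"] = {
                    "ia": round(ia.ia, 6),
                    "rbar_d": _maybe(ia.rbar_d),
                    "p_value": round(ia.p_value, 6),
                    "excluded_loci": ia.excluded_loci,
                }
            except MycopopError as e:
                manifest["warnings"].append(f"clonality/ia: {e}")
            loci_names = matrix.loci
            for i, l1 in enumerate(loci_names):
                for l2 in loci_names[i + 1 :]:
                    rep = phylogenetic_compatibility(matrix, l1, l2)
                    write_compatibility_report(rep, outdir / f"compat.{l1}-{l2}.tsv")
                    manifest["stages"].setdefault("compatibility", {})[f"{l1}-{l2}"] = {
                        "incompatible_quartets": len(rep.quartets)
                    }
    except MycopopError as e:
        (outdir / "FAILED").write_text(f"{stage}\t{e}\n")
        if isinstance(e, PipelineError):
            raise
        raise PipelineError(stage, str(e)) from e

    manifest["outputs"] = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _maybe(x: float) -> float | None:
    import math

    return None if (x != x or math.isinf(x)) else float(round(x, 6))
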