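"""End-to-end orchestration: filter -> occurrence -> richness -> null model
-> community, with a machine-readable report bundle and recorded seeds."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import (read_count_table, to_occurrence, to_rra, write_count_table,
                   write_json, write_occurrence)
from .qc import CascadeConfig, run_cascade
from .richness import accumulation, richness_summary
from .nullmodel import null_compare
from .community import (class_composition, core_zotus, dispersion_test,
                        permanova, sorensen)

logger = logging.getLogger("sharedzotu")


@dataclass
class RunConfig:
    """Inputs, stage parameters and seeds for a full pipeline run."""

    table: str = ""
    metadata: str = ""
    out_dir: str = "sharedzotu_out"
    column_map: dict = field(default_factory=dict)
    taxonomy_delimiter: str = ","
    # QC
    min_count: int = 20
    tag_jump_threshold: float = 0.0005
    control_agg: str = "max"
    drop_unassigned_domain: bool = False
    # richness
    bootstrap_b: int = 10000
    accumulation_n_rand: int = 200
    # null model
    null_n_rand: int = 1000
    null_mass: float = 0.95
    null_method: str = "quasiswap"
    # community
    n_perm: int = 10000
    k_core: int = 50
    # seeds: a master seed from which every randomized stage gets its own
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def stage_seeds(self) -> dict:
        """Deterministic per-stage seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("accumulation", "richness_bootstrap", "nullmodel", "permanova")
        states = ss.generate_state(len(names), dtype=np.uint32)
        return {name: int(state % (2 ** 31)) for name, state in zip(names, states)}


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline; write the report bundle; return file paths.

    Outputs under ``config.out_dir``: ``filtered.tsv``, ``filter_report.json``,
    ``occurrence.tsv``, ``richness.tsv``, ``null_summary.json``,
    ``community.json`` and ``provenance.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()

    table, metadata = read_count_table(
        config.table, config.metadata,
        column_map=config.column_map or None,
        taxonomy_delimiter=config.taxonomy_delimiter)

    cascade_cfg = CascadeConfig(
        min_count=config.min_count,
        tag_jump_threshold=config.tag_jump_threshold,
        control_agg=config.control_agg,
        drop_unassigned_domain=config.drop_unassigned_domain,
        taxonomy_delimiter=config.taxonomy_delimiter)
    filtered, report = run_cascade(table, metadata, cascade_cfg)
    write_count_table(filtered, out / "filtered.tsv",
                      taxonomy_delimiter=config.taxonomy_delimiter)
    write_json(report.to_dict(), out / "filter_report.json")

    occurrence = to_occurrence(filtered, metadata)
    dropped = sorted(set(metadata.individuals) - set(occurrence.individual_ids))
    if dropped:
        logger.warning("individuals dropped (no surviving ZOTUs): %s", dropped)
    write_occurrence(occurrence, out / "occurrence.tsv")
    rra = to_rra(filtered.copy())

    rich = richness_summary(occurrence, B=config.bootstrap_b,
                            seed=seeds["richness_bootstrap"])
    rich.index.name = "species"
    rich.to_csv(out / "richness.tsv", sep="\t")
    acc_seed = np.random.SeedSequence(seeds["accumulation"])
    curves = {sp: accumulation(occurrence, sp, n_rand=config.accumulation_n_rand,
                               seed=child).mean_curve.tolist()
              for sp, child in zip(occurrence.species,
                                   acc_seed.spawn(len(occurrence.species)))}

    null = null_compare(occurrence, n_rand=config.null_n_rand,
                        mass=config.null_mass, seed=seeds["nullmodel"],
                        method=config.null_method)
    write_json(null.to_dict(), out / "null_summary.json")

    dist = sorensen(occurrence)
    groups = [occurrence.partition[i] for i in dist.ids]
    disp = dispersion_test(dist, groups)
    perm = permanova(dist, groups, n_perm=config.n_perm, seed=seeds["permanova"])
    rra_for_occurrence = rra.values.reindex(
        index=occurrence.zotu_ids, columns=occurrence.individual_ids).fillna(0.0)
    composition = class_composition(
        type(rra)(rra_for_occurrence.div(rra_for_occurrence.sum(axis=0), axis=1)),
        filtered.taxonomy, occurrence.partition)
    cores = core_zotus(rra, occurrence,
                       k=min(config.k_core, len(occurrence.zotu_ids)))
    community = {
        "permanova": {"pseudo_f": perm.pseudo_f, "r2": perm.r2, "p": perm.p,
                      "n_perm": perm.n_perm, "n_groups": perm.n_groups,
                      "n_samples": perm.n_samples},
        "dispersion": {"f": disp.f, "df1": disp.df1, "df2": disp.df2,
                       "p": disp.p, "group_means": disp.group_means},
        "core_zotus": list(cores),
        "class_composition_percent": {sp: row.to_dict()
                                      for sp, row in composition.iterrows()},
        "accumulation_mean_curves": curves,
        "dropped_individuals": dropped,
    }
    write_json(community, out / "community.json")

    provenance = {"version": __version__, "config": asdict(config),
                  "stage_seeds": seeds}
    write_json(provenance, out / "provenance.json")
    return {name: str(out / name) for name in
            ("filtered.tsv", "filter_report.json", "occurrence.tsv",
             "richness.tsv", "null_summary.json", "community.json",
             "provenance.json")}
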