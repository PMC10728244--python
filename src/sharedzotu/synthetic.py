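"""Synthetic replicated ZOTU datasets with known ground truth.

The generator emulates the statistical structure of a multi-host-species
faecal 16S survey so that every analysis stage is testable without field
data:

* a few host species, each with a fixed number of sampled individuals;
* a minority of *core* ZOTUs shared across species — each core has one
  presence probability, drawn once and applied to every individual
  regardless of species, so that at no injected effect the matrix is
  column-exchangeable and matches its own fixed-fixed null;
* a majority of *incidental* ZOTUs — placed neutrally across all individuals
  at a per-individual probability of about 1/(total individuals)
  (zero-truncated), so each is seen in ≈1 individual and hence usually in
  one species. Neutral placement keeps the no-effect matrix
  column-exchangeable: with no injected surfeit the generator matches its
  own fixed-margin null;
* an optional *surfeit*: ``specific_excess > 1`` adds
  ``(specific_excess - 1) * n_specific`` extra ZOTUs genuinely restricted to
  one designated species' individuals — the synthetic analogue of a host
  species carrying an excess of non-shared microbes;
* counts: per-individual sequencing depth is lognormal, per-ZOTU expected
  shares are Dirichlet (cores concentrated higher than specifics), and each
  of the two technical replicates is an independent gamma-perturbed
  multinomial, calibrated so the median paired-replicate percentage
  difference in counts is ≈50%;
* contamination: dedicated contaminant ZOTUs appear in extraction/PCR
  controls and, at low level and sporadically, in sample replicates; a few
  off-target (non-bacterial / chloroplast) rows exercise the taxonomy
  filter.

Presence and abundance are generated in two stages (occupancy first, then
counts) so occurrence-level tests do not depend on the count noise model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import CountTable, OccurrenceMatrix, RANKS, SampleMetadata

#: Bacterial classes used for synthetic taxonomy, weighted the way a
#: freshwater-insect faecal survey tends to look (Gammaproteobacteria and
#: Bacilli dominant).
CLASS_POOL = (
    ("Proteobacteria", "Gammaproteobacteria", 0.45),
    ("Firmicutes", "Bacilli", 0.25),
    ("Proteobacteria", "Alphaproteobacteria", 0.10),
    ("Proteobacteria", "Betaproteobacteria", 0.07),
    ("Actinobacteria", "Actinobacteria", 0.07),
    ("Tenericutes", "Mollicutes", 0.03),
    ("Bacteroidetes", "Sphingobacteria", 0.03),
)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the scaled study conditions
    (~400 ZOTUs x 40 individuals across 4 species) used throughout the test
    suite. :meth:`paper_scale` switches to the full survey dimensions."""

    n_species: int = 4
    individuals_per_species: tuple = (10, 10, 10, 10)
    n_core: int = 120
    core_prevalence_range: tuple = (0.05, 0.5)
    n_specific: int = 70                  # incidental ZOTUs per species
    specific_prevalence: float | None = None   # default 1 / total individuals
    specific_excess: float = 1.0          # >= 1; 1 means no surfeit
    excess_species: int = 0               # index of the designated species
    excess_prevalence_factor: float = 3.0  # surfeit within-species prevalence,
                                           # in units of 1 / total individuals
    read_depth_log_mean: float = math.log(4.0e4)
    read_depth_log_sd: float = 0.5
    replicate_cv: float = 0.5
    dirichlet_core: float = 3.0
    dirichlet_specific: float = 1.0
    n_contaminants: int = 15
    control_contamination_mean: float = 30.0
    sample_contamination_rate: float = 0.3
    sample_contamination_mean: float = 10.0
    n_offtarget: int = 5
    n_extraction_controls: int = 2
    n_pcr_controls: int = 2
    resample_empty: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.individuals_per_species) != self.n_species:
            raise ValueError("individuals_per_species length must equal n_species")
        lo, hi = self.core_prevalence_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("core_prevalence_range must be within [0, 1]")
        if self.specific_excess < 1:
            raise ValueError("specific_excess must be >= 1 (1 = no surfeit)")

    @classmethod
    def paper_scale(cls, **overrides) -> "SyntheticConfig":
        """Full survey dimensions: ~1,500 ZOTUs over 185 individuals."""
        kw = dict(
            individuals_per_species=(48, 46, 46, 45),
            n_core=560,
            n_specific=240,
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def species_names(self) -> list:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    @property
    def n_individuals(self) -> int:
        return int(sum(self.individuals_per_species))

    @property
    def n_excess(self) -> int:
        """Extra ZOTUs restricted to the designated species."""
        return int(round((self.specific_excess - 1) * self.n_specific))


@dataclass
class GroundTruth:
    """What the generator knows: per-ZOTU class, owner, presence probs."""

    zotu_class: pd.Series            # zotu -> core | specific | contaminant | offtarget
    owner: pd.Series                 # zotu -> owning species ("" for cores etc.)
    presence_prob: pd.DataFrame      # zotu x species presence probability
    total_richness: int
    config: SyntheticConfig = None

    def to_dict(self) -> dict:
        return {
            "zotu_class": self.zotu_class.to_dict(),
            "owner": self.owner.to_dict(),
            "total_richness": self.total_richness,
            "config": asdict(self.config) if self.config else None,
        }


def _individual_ids(config: SyntheticConfig) -> tuple:
    ids, species = [], []
    for s, n in zip(config.species_names, config.individuals_per_species):
        for i in range(n):
            ids.append(f"{s}_i{i + 1:02d}")
            species.append(s)
    return ids, pd.Series(species, index=ids)


def _bernoulli_rows(rng, n_rows, probs_per_col, resample):
    """Sample independent Bernoulli rows; optionally resample all-zero rows
    (zero-truncated occupancy)."""
    out = (rng.random((n_rows, probs_per_col.shape[-1])) < probs_per_col)
    if resample:
        for _ in range(10000):
            empty = ~out.any(axis=1)
            if not empty.any():
                break
            out[empty] = (rng.random((int(empty.sum()), out.shape[1]))
                          < (probs_per_col[empty] if probs_per_col.ndim == 2
                             else probs_per_col))
    return out.astype(np.int8)


def generate_occurrence(config: SyntheticConfig, rng=None):
    """Sample the true occurrence matrix and its ground truth.

    Returns ``(OccurrenceMatrix, GroundTruth)``. Deterministic for a fixed
    ``config.seed`` (or a supplied generator).
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    ind_ids, partition = _individual_ids(config)
    n_ind = len(ind_ids)
    spec_p = config.specific_prevalence or 1.0 / n_ind

    rows, zotu_ids, classes, owners = [], [], [], []
    prob_rows = []

    lo, hi = config.core_prevalence_range
    core_p = rng.uniform(lo, hi, size=config.n_core)
    core = _bernoulli_rows(rng, config.n_core,
                           np.repeat(core_p[:, None], n_ind, axis=1),
                           config.resample_empty)
    for z in range(config.n_core):
        zotu_ids.append(f"core{z + 1:04d}")
        classes.append("core")
        owners.append("")
        prob_rows.append({s: core_p[z] for s in config.species_names})
    rows.append(core)

    # incidental ZOTUs: neutral across all individuals, zero-truncated, so the
    # no-surfeit matrix is column-exchangeable and matches its own null
    n_base = config.n_species * config.n_specific
    base = _bernoulli_rows(rng, n_base,
                           np.full((n_base, n_ind), spec_p),
                           config.resample_empty)
    rows.append(base)
    for z in range(n_base):
        zotu_ids.append(f"spec{z + 1:04d}")
        classes.append("specific")
        owners.append("")
        prob_rows.append({s: spec_p for s in config.species_names})

    # the injected surfeit: extra ZOTUs confined to the designated species
    n_excess = config.n_excess
    if n_excess:
        sp = config.species_names[config.excess_species]
        col_of = {ind: j for j, ind in enumerate(ind_ids)}
        own_cols = [col_of[i] for i in ind_ids if partition[i] == sp]
        exc_p = config.excess_prevalence_factor / n_ind
        block = np.zeros((n_excess, n_ind), dtype=np.int8)
        block[:, own_cols] = _bernoulli_rows(
            rng, n_excess, np.full((n_excess, len(own_cols)), exc_p),
            config.resample_empty)
        rows.append(block)
        for z in range(n_excess):
            zotu_ids.append(f"exspec_{sp}_{z + 1:04d}")
            classes.append("specific")
            owners.append(sp)
            prob_rows.append({s: (exc_p if s == sp else 0.0)
                              for s in config.species_names})

    arr = np.vstack(rows)
    presence = pd.DataFrame(arr, index=zotu_ids, columns=ind_ids)
    empty_rows = presence.sum(axis=1) == 0
    if empty_rows.any():
        presence = presence[~empty_rows]
    empty_cols = presence.sum(axis=0) == 0
    if empty_cols.any():
        presence = presence.loc[:, ~empty_cols]
    if presence.empty:
        raise ValueError("configuration produced an empty occurrence matrix")
    truth = GroundTruth(
        zotu_class=pd.Series(classes, index=zotu_ids).loc[presence.index],
        owner=pd.Series(owners, index=zotu_ids).loc[presence.index],
        presence_prob=pd.DataFrame(prob_rows, index=zotu_ids).loc[presence.index],
        total_richness=len(presence),
        config=config,
    )
    matrix = OccurrenceMatrix(presence, partition.loc[presence.columns])
    return matrix, truth


def _synthetic_taxonomy(rng, zotu_ids, zotu_class) -> pd.DataFrame:
    weights = np.array([w for _, _, w in CLASS_POOL])
    weights = weights / weights.sum()
    tax = pd.DataFrame("", index=zotu_ids, columns=list(RANKS))
    for z in zotu_ids:
        kind = zotu_class[z]
        if kind == "offtarget":
            if rng.random() < 0.5:
                tax.loc[z] = ["Viridiplantae", "Streptophyta", "", "", "", ""]
            else:
                tax.loc[z] = ["Bacteria", "Cyanobacteria", "Chloroplast",
                              "", "", ""]
            continue
        phylum, klass, _ = CLASS_POOL[rng.choice(len(CLASS_POOL), p=weights)]
        # genus labels are unique per ZOTU so that taxonomy collapsing keeps
        # synthetic identities distinct (real collapsing is exercised by
        # dedicated fixtures)
        tax.loc[z] = ["Bacteria", phylum, klass, "", "", f"Genus-{z}"]
    return tax


def generate_counts(config: SyntheticConfig, occurrence: OccurrenceMatrix,
                    truth: GroundTruth | None = None, rng=None):
    """Replicate-level counts (two replicates per individual, plus controls).

    Per individual: total depth lognormal; expected per-ZOTU shares Dirichlet
    over present ZOTUs (cores get higher concentration); each replicate an
    independent gamma-perturbed multinomial with CV ``replicate_cv``.
    Contaminant and off-target rows are appended afterwards.

    Returns ``(CountTable, SampleMetadata)``.
    """
    rng = np.random.default_rng(config.seed + 1 if (rng is None and
                                config.seed is not None) else rng)
    pres = occurrence.presence
    zotu_ids = list(pres.index)
    if truth is not None:
        alpha_class = truth.zotu_class.map(
            {"core": config.dirichlet_core}).fillna(config.dirichlet_specific)
        zotu_class = truth.zotu_class.copy()
    else:
        alpha_class = pd.Series(config.dirichlet_core, index=zotu_ids)
        zotu_class = pd.Series("core", index=zotu_ids)

    cv = config.replicate_cv
    shape = 1.0 / cv ** 2 if cv > 0 else None

    replicate_cols = {}
    meta_rows = []
    for ind in pres.columns:
        present = pres[ind].to_numpy().astype(bool)
        idx = np.flatnonzero(present)
        alpha = alpha_class.iloc[idx].to_numpy()
        share = rng.gamma(alpha, 1.0)
        share = share / share.sum()
        depth = rng.lognormal(config.read_depth_log_mean, config.read_depth_log_sd)
        for r in (1, 2):
            rep_id = f"{ind}_r{r}"
            if shape is not None:
                mult = rng.gamma(shape, 1.0 / shape, size=share.size)
            else:
                mult = np.ones_like(share)
            probs = share * mult
            probs = probs / probs.sum()
            n_reads = int(rng.poisson(depth / 2))
            counts = rng.multinomial(max(n_reads, 1), probs)
            col = np.zeros(len(zotu_ids), dtype=np.int64)
            col[idx] = counts
            replicate_cols[rep_id] = col
            meta_rows.append((rep_id, ind, occurrence.partition[ind], "none"))

    control_ids = ([f"ctrl_ext{i + 1}" for i in range(config.n_extraction_controls)]
                   + [f"ctrl_pcr{i + 1}" for i in range(config.n_pcr_controls)])
    control_kinds = (["extraction"] * config.n_extraction_controls
                     + ["pcr"] * config.n_pcr_controls)
    for cid, kind in zip(control_ids, control_kinds):
        replicate_cols[cid] = np.zeros(len(zotu_ids), dtype=np.int64)
        meta_rows.append((cid, "", "", kind))

    counts = pd.DataFrame(replicate_cols, index=zotu_ids)

    # contaminant rows: in controls always, in sample replicates sporadically
    extra_rows = {}
    extra_class = {}
    sample_reps = [r for r, _, _, kind in meta_rows if kind == "none"]
    for z in range(config.n_contaminants):
        zid = f"contam{z + 1:03d}"
        row = pd.Series(0, index=counts.columns, dtype=np.int64)
        for cid in control_ids:
            row[cid] = max(int(rng.poisson(config.control_contamination_mean)), 1)
        hit = rng.random(len(sample_reps)) < config.sample_contamination_rate
        row[np.array(sample_reps)[hit]] = rng.poisson(
            config.sample_contamination_mean, size=int(hit.sum()))
        extra_rows[zid] = row
        extra_class[zid] = "contaminant"
    # off-target rows: solid counts in both replicates of some individuals,
    # removable only by the taxonomy filter
    individuals = list(pres.columns)
    for z in range(config.n_offtarget):
        zid = f"offtarget{z + 1:03d}"
        row = pd.Series(0, index=counts.columns, dtype=np.int64)
        chosen = rng.random(len(individuals)) < 0.3
        for ind in np.array(individuals)[chosen]:
            for r in (1, 2):
                row[f"{ind}_r{r}"] = rng.poisson(150) + 20
        extra_rows[zid] = row
        extra_class[zid] = "offtarget"
    if extra_rows:
        counts = pd.concat([counts, pd.DataFrame(extra_rows).T])

    all_class = pd.concat([zotu_class, pd.Series(extra_class)])
    taxonomy = _synthetic_taxonomy(rng, list(counts.index), all_class)
    table = CountTable(counts, taxonomy)
    meta = pd.DataFrame(meta_rows, columns=["replicate_id", "individual_id",
                                            "host_species", "control_kind"])
    metadata = SampleMetadata(meta.set_index("replicate_id"))
    if truth is not None:
        truth.zotu_class = all_class
    return table, metadata


def generate_dataset(config: SyntheticConfig):
    """Occurrence + counts + metadata + truth in one deterministic call."""
    rng = np.random.default_rng(config.seed)
    occurrence, truth = generate_occurrence(config, rng=rng)
    table, metadata = generate_counts(config, occurrence, truth, rng=rng)
    return table, metadata, occurrence, truth
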