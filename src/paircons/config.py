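"""Run configuration and the end-to-end pipeline driver.

A run is fully described by a YAML-serializable :class:`RunConfig`; rerunning
the same config over the same inputs produces byte-identical outputs.  All
randomness flows from the single config-level seed; each stochastic stage
derives its own seed by stable hashing of ``(root seed, stage name)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import _tsv
from .align import align_group, read_codon_alignment, write_codon_alignment
from .codes import load_genetic_code, pair_label, parse_pair, SUPPORTED_TABLES
from .conservation import (
    accumulate_conservation,
    orf_conservation_rates,
    orf_rate_summary,
    shifted_frame_conservation,
)
from .errors import ConfigError
from .io import OrfFilter, apply_orf_filter, read_fasta, read_ortholog_table
from .model import CodonPairConservation, frame_shift_control
from .positions import (
    collect_occurrences,
    fisher_enrichment,
    occurrence_positions,
    simulate_random_sets,
)
from .properties import (
    chisq_categories,
    define_orf_sets,
    polysome_contingency,
    summarize_sets,
)
from .simulate import (
    PlantedPair,
    SyntheticSpec,
    emit_property_table,
    generate,
    to_alignments,
    write_dataset,
)

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    reference: str = "ref"
    species: tuple[str, ...] = ()
    code_table: int = 1
    placeholder: str = "---"
    require_all_species: bool = True
    pseudocount: float | str = "auto"
    k_sigma: float = 3.0
    frames: tuple[int, ...] = (0, 1, 2)
    min_species_conserved: int = 4
    focal_pairs: tuple[str, ...] = ()
    control_pairs: tuple[str, ...] = ()
    n_random_sets: int = 100
    random_set_size: int = 9
    positions_conserved_only: bool = True
    exclude_focal_from_random: bool = True
    seed: int = 0
    #: SyntheticSpec fields (dict) to simulate inputs; None = real inputs
    simulate: dict | None = None
    #: real-input paths: orf_dir, ortholog_table, exclusion_list,
    #: alignments_dir (pre-aligned codon FASTA; skips the aligner)
    inputs: dict | None = None
    property_table: str | None = None
    property_shifts: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.species = tuple(cfg.species)
        cfg.frames = tuple(cfg.frames)
        cfg.focal_pairs = tuple(cfg.focal_pairs)
        cfg.control_pairs = tuple(cfg.control_pairs)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("species", "frames", "focal_pairs", "control_pairs"):
            d[key] = list(d[key])
        return d

    def sha256(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.code_table not in SUPPORTED_TABLES:
            raise ConfigError(
                f"code_table must be one of {SUPPORTED_TABLES}")
        if self.simulate is None and self.inputs is None:
            raise ConfigError("config needs either 'simulate' or 'inputs'")
        if self.simulate is None:
            if not self.species:
                raise ConfigError("real-input runs must list species")
            if self.reference not in self.species:
                raise ConfigError(
                    f"reference {self.reference!r} not in species "
                    f"{list(self.species)}")
        for frame_offset in self.frames:
            if frame_offset not in (0, 1, 2):
                raise ConfigError("frames must be subset of (0, 1, 2)")
        if 0 not in self.frames:
            raise ConfigError("frame 0 is required")
        for label in tuple(self.focal_pairs) + tuple(self.control_pairs):
            parse_pair(label)


def _build_spec(config: RunConfig) -> SyntheticSpec:
    raw = dict(config.simulate or {})
    if "planted_pairs" in raw:
        raw["planted_pairs"] = tuple(
            PlantedPair(
                pair=parse_pair(p["pair"]),
                lock_fraction=p.get("lock_fraction", 0.4),
                occurrences=p.get("occurrences", 50),
            )
            for p in raw["planted_pairs"]
        )
    if "gene_length_range" in raw:
        raw["gene_length_range"] = tuple(raw["gene_length_range"])
    raw.setdefault("seed", stage_seed(config.seed, "simulate"))
    raw.setdefault("code_table", config.code_table)
    return SyntheticSpec(**raw)


def _load_real_alignments(config: RunConfig):
    inputs = config.inputs or {}
    code = load_genetic_code(config.code_table)
    if "alignments_dir" in inputs:
        paths = sorted(Path(inputs["alignments_dir"]).glob("*.fasta"))
        return [read_codon_alignment(p, config.reference) for p in paths]
    orf_dir = Path(inputs["orf_dir"])
    seqs = {
        sp: dict(read_fasta(orf_dir / f"{sp}.fasta"))
        for sp in config.species
    }
    groups = read_ortholog_table(
        inputs["ortholog_table"], config.species,
        placeholder=config.placeholder, reference=config.reference)
    if "exclusion_list" in inputs:
        groups = apply_orf_filter(
            groups, OrfFilter.from_file(inputs["exclusion_list"]),
            config.reference)
    groups = [g.with_sequences(seqs) for g in groups]
    if config.require_all_species:
        groups = [g for g in groups
                  if set(config.species) <= set(g.species)]
    else:
        groups = [g for g in groups if config.reference in g.species]
    return [align_group(g, code, reference=config.reference) for g in groups]


def run_all(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the full pipeline and populate ``outdir`` with TSV outputs.

    Stages: simulate (optional) -> align -> conservation (frames 0/1/2) ->
    origin-fit model + scores/z -> positional analysis -> gene properties.
    Returns the in-memory results keyed by stage.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    code = load_genetic_code(config.code_table)
    meta = {"config_sha256": config.sha256(), "seed": config.seed}

    def stamp(stage: str) -> dict:
        return dict(meta, stage=stage)

    results: dict[str, Any] = {}

    # ---- inputs --------------------------------------------------------
    dataset = None
    if config.simulate is not None:
        spec = _build_spec(config)
        dataset = generate(spec)
        write_dataset(dataset, outdir / "data")
        alignments = to_alignments(dataset, code)
        focal = tuple(
            pair_label(*p.pair) for p in spec.planted_pairs)
    else:
        alignments = _load_real_alignments(config)
        focal = config.focal_pairs
    if config.focal_pairs:
        focal = config.focal_pairs
    focal_pairs = [parse_pair(p) for p in focal]
    control = config.control_pairs or tuple(
        pair_label(b, a) for a, b in focal_pairs)
    control_pairs = [parse_pair(p) for p in control]
    results["n_alignments"] = len(alignments)
    results["focal_pairs"] = focal_pairs
    if dataset is not None:
        results["truth"] = dataset.truth

    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for aln in alignments:
        write_codon_alignment(aln, aln_dir / f"{aln.group_id}.fasta")

    # ---- conservation --------------------------------------------------
    tables = {}
    for frame_offset in sorted(config.frames):
        if frame_offset == 0:
            tables[0] = accumulate_conservation(alignments, code)
        else:
            tables[frame_offset] = shifted_frame_conservation(
                alignments, frame_offset, code)
        suffix = "" if frame_offset == 0 else f"_frame{frame_offset}"
        _tsv.write_table(
            tables[frame_offset].codon_dataframe(),
            outdir / f"conservation_codons{suffix}.tsv", stamp("conserve"))
        _tsv.write_table(
            tables[frame_offset].pair_dataframe(),
            outdir / f"conservation_pairs{suffix}.tsv", stamp("conserve"))
    orfs = orf_conservation_rates(alignments)
    _tsv.write_table(
        pd.DataFrame([{
            "orf_id": o.orf_id, "length_codons": o.length_codons,
            "conserved_codons": o.conserved_codons, "rate": o.rate,
        } for o in orfs]),
        outdir / "orf_rates.tsv", stamp("conserve"))
    results["tables"] = tables
    results["orf_rates"] = orf_rate_summary(orfs)

    # ---- model ---------------------------------------------------------
    model = CodonPairConservation(
        tables[0], code=code, pseudocount=config.pseudocount)
    res = model.fit(k_sigma=config.k_sigma)
    _tsv.write_table(res.pair_table(), outdir / "pair_fit.tsv",
                     stamp("model"))
    _tsv.write_table(res.normalized.frame, outdir / "normalized_scores.tsv",
                     stamp("model"))
    _tsv.write_table(res.dipeptide_z, outdir / "dipeptide_z.tsv",
                     stamp("model"))
    _tsv.write_text(res.summary(), outdir / "model_summary.txt",
                    stamp("model"))
    if len(tables) > 1:
        fsz = frame_shift_control(tables, focal_pairs, code,
                                  config.pseudocount)
        _tsv.write_table(fsz, outdir / "frameshift_z.tsv", stamp("model"))
        results["frameshift_z"] = fsz
    results["model"] = res

    # ---- positions -----------------------------------------------------
    occurrences = collect_occurrences(alignments, focal_pairs)
    occ_df = pd.DataFrame([{
        "orf_id": o.orf_id, "pair": pair_label(*o.pair),
        "start_codon_index": o.start_codon_index,
        "orf_length_codons": o.orf_length_codons,
        "relative_position": o.relative_position,
        "conserved": o.conserved,
    } for o in occurrences])
    _tsv.write_table(occ_df, outdir / "occurrences.tsv", stamp("positions"))
    universe = occurrence_positions(
        alignments, config.code_table,
        conserved_only=config.positions_conserved_only)
    exclude = focal_pairs if config.exclude_focal_from_random else ()
    if len(universe) >= config.random_set_size + len(list(exclude)):
        sim = simulate_random_sets(
            universe, n_sets=config.n_random_sets,
            set_size=config.random_set_size,
            seed=stage_seed(config.seed, "positions"), exclude=exclude)
        _tsv.write_table(
            pd.DataFrame({"set_index": range(sim.n_sets),
                          "median_position": sim.medians}),
            outdir / "simulation_medians.tsv", stamp("positions"))
        _tsv.write_table(
            pd.DataFrame([{
                "n_sets": sim.n_sets, "set_size": sim.set_size,
                "seed": sim.seed, "mean_of_medians": sim.mean_of_medians,
                "sd_of_medians": sim.sd_of_medians,
            }]),
            outdir / "simulation_summary.tsv", stamp("positions"))
        results["positions"] = sim
    # enrichment of the focal set among above-line outliers
    n_pairs = len(res.fit_result.frame)
    above = res.outliers_above
    focal_set = set(focal_pairs)
    a = len(focal_set & above)
    b = len(focal_set) - a
    c = len(above - focal_set)
    d = n_pairs - a - b - c
    p_enrich = fisher_enrichment(a, b, c, d)
    _tsv.write_table(
        pd.DataFrame([{
            "focal_outliers": a, "focal_non_outliers": b,
            "other_outliers": c, "other_non_outliers": d,
            "fisher_p_greater": p_enrich,
        }]),
        outdir / "enrichment.tsv", stamp("positions"))
    results["enrichment_p"] = p_enrich

    # ---- gene properties ----------------------------------------------
    sets = define_orf_sets(alignments, focal_pairs, control_pairs,
                           min_species=config.min_species_conserved)
    results["orf_sets"] = sets
    if config.property_table is not None:
        props = _tsv.read_table(config.property_table)
    elif dataset is not None:
        props = emit_property_table(
            dataset, focal_orfs=sets.focal, control_orfs=sets.control,
            shifts=config.property_shifts,
            seed=stage_seed(config.seed, "properties"))
        _tsv.write_table(props, outdir / "properties_synthetic.tsv",
                         stamp("properties"))
    else:
        props = None
    if props is not None:
        summary = summarize_sets(props, sets)
        _tsv.write_table(summary, outdir / "table1_like.tsv",
                         stamp("properties"))
        results["property_summary"] = summary
        contingency = polysome_contingency(props, sets)
        nonzero = contingency.loc[contingency.sum(axis=1) > 0]
        if len(nonzero) >= 2 and (contingency.sum(axis=0) > 0).sum() >= 2:
            stat, dof, p = chisq_categories(contingency)
            chi_df = contingency.reset_index(names="set")
            chi_df["chisq"] = stat
            chi_df["dof"] = dof
            chi_df["p_value"] = p
            _tsv.write_table(chi_df, outdir / "polysome_chisq.tsv",
                             stamp("properties"))
            results["polysome_chisq"] = (stat, dof, p)
    return results
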