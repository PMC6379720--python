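"""Synthetic multi-species ortholog sets with planted conserved codon pairs.

The generator emulates the statistical structure the downstream analysis
assumes, without pretending to be a population-genetic model: ancestral
coding sequences are drawn codon-wise from a codon frequency vector, and
each non-reference species is derived *independently* from the ancestor
(star phylogeny; the reference species keeps the ancestral sequence) by

* synonymous substitution with a fixed per-codon probability (replacement
  drawn uniformly from the codon's synonymous class, excluding itself), so
  expected per-codon conservation is ``(1 - p_sub) ** (n_species - 1)``;
* optional nonsynonymous substitution (uniform over different-amino-acid
  sense codons); and
* optional codon-level indels, which is what exercises the aligner path.

Planted codon pairs are written into the ancestor at non-overlapping random
positions; a configurable fraction of each pair's occurrences is *locked* —
copied verbatim into every species, never mutated — creating positions
whose pair conservation exceeds the product of the constituent codon
conservation rates, the signal the pipeline is built to detect.  A truth
record carries every planted occurrence, per-ORF conserved-codon ground
truth, and the realized totals, so tests can check recovery exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import CodonAlignment, align_group
from .codes import (
    CODON_INDEX,
    CODONS,
    GeneticCode,
    load_genetic_code,
    pair_label,
    synonymous_partners,
)
from .errors import SimulationError
from .io import OrthologGroup, OrthologMember, write_fasta
from .properties import POLYSOME_CATEGORIES

Pair = tuple[str, str]

_CODON_ARR = np.array(CODONS)

#: Default planted pairs: built from the slow, wobble-decoded codons that
#: dominate inhibitory codon pairs in budding yeast (CGA, CCG, ATA, CTC,
#: GCG, GTA, CTG), one pair per ordered dipeptide family so each planted
#: pair is the unique extreme within its family.
DEFAULT_PLANTED_PAIRS: tuple[Pair, ...] = (
    ("CGA", "CGA"),  # Arg-Arg
    ("CGA", "CCG"),  # Arg-Pro
    ("CTC", "CCG"),  # Leu-Pro
    ("CGA", "ATA"),  # Arg-Ile
    ("ATA", "CGG"),  # Ile-Arg
    ("GTA", "CGA"),  # Val-Arg
    ("CGA", "GCG"),  # Arg-Ala
    ("GCG", "GTA"),  # Ala-Val
    ("CCG", "CTC"),  # Pro-Leu
)


@dataclass(frozen=True)
class PlantedPair:
    pair: Pair
    lock_fraction: float = 0.4
    occurrences: int = 50


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic genome set.

    Defaults are the conditions the pipeline's recovery experiments run
    under: 5 species, 500 genes of 100–600 codons, uniform sense-codon
    usage, 0.3 synonymous substitutions per codon per branch, and nine
    planted pairs with 40% of 50 occurrences locked.
    """

    n_species: int = 5
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (100, 600)
    codon_frequencies: str | Sequence[float] = "uniform"
    substitution_prob: float = 0.3
    nonsynonymous_prob: float = 0.0
    indel_prob: float = 0.0
    planted_pairs: tuple[PlantedPair, ...] = field(
        default_factory=lambda: tuple(
            PlantedPair(p) for p in DEFAULT_PLANTED_PAIRS))
    code_table: int = 1
    seed: int = 0

    @property
    def species_ids(self) -> tuple[str, ...]:
        return ("ref",) + tuple(f"sp{i}" for i in range(1, self.n_species))

    @property
    def reference(self) -> str:
        return "ref"

    def validate(self) -> None:
        if not 2 <= self.n_species:
            raise SimulationError("need >=2 species")
        lo, hi = self.gene_length_range
        if not (2 <= lo <= hi):
            raise SimulationError("gene_length_range must satisfy 2<=min<=max")
        for p in (self.substitution_prob, self.nonsynonymous_prob,
                  self.indel_prob):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("probabilities must be in [0, 1]")
        code = load_genetic_code(self.code_table)
        for pp in self.planted_pairs:
            for codon in pp.pair:
                if code.is_stop(codon):
                    raise SimulationError(
                        f"planted pair {pair_label(*pp.pair)} contains a stop")
            if not 0.0 <= pp.lock_fraction <= 1.0:
                raise SimulationError("lock_fraction must be in [0, 1]")
        if not isinstance(self.codon_frequencies, str):
            freqs = np.asarray(self.codon_frequencies, dtype=float)
            if len(freqs) != len(code.sense_codons):
                raise SimulationError(
                    f"codon_frequencies needs {len(code.sense_codons)} entries")
            if abs(float(freqs.sum()) - 1.0) > 1e-9:
                raise SimulationError("codon_frequencies must sum to 1")


@dataclass
class TruthRecord:
    """Ground truth for one generated dataset."""

    #: one entry per planted occurrence:
    #: {orf_id, pair, start_codon_index (1-based), locked}
    planted_occurrences: list[dict]
    #: reference ORF id -> (length_codons, conserved_codons); None when
    #: indels make positional truth ill-defined
    orf_conserved: dict[str, tuple[int, int]] | None
    #: pair label -> {"total": n, "conserved": k} realized in the emitted
    #: sequences for each planted pair (None when indels enabled)
    realized_planted: dict[str, dict[str, int]] | None
    #: expected pair/codon-product conservation ratio for unplanted pairs
    #: (1.0: codons diverge independently under the star process)
    neutral_coupling: float = 1.0

    def focal_orfs(self, locked_only: bool = True) -> frozenset[str]:
        return frozenset(
            occ["orf_id"] for occ in self.planted_occurrences
            if occ["locked"] or not locked_only)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_occurrences": self.planted_occurrences,
            "orf_conserved": self.orf_conserved,
            "realized_planted": self.realized_planted,
            "neutral_coupling": self.neutral_coupling,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        orf = payload["orf_conserved"]
        if orf is not None:
            orf = {k: tuple(v) for k, v in orf.items()}
        return cls(
            planted_occurrences=payload["planted_occurrences"],
            orf_conserved=orf,
            realized_planted=payload["realized_planted"],
            neutral_coupling=payload["neutral_coupling"],
        )


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    #: species -> [(orf_id, codon-id array)] in gene order
    genes: dict[str, list[np.ndarray]]
    truth: TruthRecord

    @property
    def reference(self) -> str:
        return self.spec.reference

    def orf_id(self, species: str, gene_index: int) -> str:
        return f"{species}_{gene_index:04d}"

    def sequences(self, species: str) -> list[tuple[str, str]]:
        return [
            (self.orf_id(species, i), "".join(_CODON_ARR[ids]))
            for i, ids in enumerate(self.genes[species])
        ]

    def ortholog_rows(self) -> list[tuple[str, ...]]:
        return [
            tuple(self.orf_id(sp, i) for sp in self.spec.species_ids)
            for i in range(self.spec.n_genes)
        ]

    def groups(self) -> list[OrthologGroup]:
        out = []
        for i in range(self.spec.n_genes):
            members = {
                sp: OrthologMember(
                    self.orf_id(sp, i), "".join(_CODON_ARR[self.genes[sp][i]]))
                for sp in self.spec.species_ids
            }
            out.append(OrthologGroup(self.orf_id(self.reference, i), members))
        return out


def _ragged(lists: Mapping[int, Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
    """Pack per-codon alternative lists into a (64, max) matrix + counts."""
    counts = np.zeros(64, dtype=np.int64)
    width = max((len(v) for v in lists.values()), default=1) or 1
    mat = np.zeros((64, width), dtype=np.int64)
    for cid, alts in lists.items():
        counts[cid] = len(alts)
        mat[cid, :len(alts)] = alts
    return mat, counts


def _mutate(ids: np.ndarray, mask: np.ndarray, mat: np.ndarray,
            counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace masked codons with a uniform draw from their alternatives."""
    out = ids.copy()
    pos = np.nonzero(mask)[0]
    if len(pos) == 0:
        return out
    cur = out[pos]
    n_alt = counts[cur]
    usable = n_alt > 0
    pos, cur, n_alt = pos[usable], cur[usable], n_alt[usable]
    if len(pos):
        choice = rng.integers(0, n_alt)
        out[pos] = mat[cur, choice]
    return out


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate one dataset; deterministic for a fixed ``spec.seed``."""
    spec.validate()
    code = load_genetic_code(spec.code_table)
    rng = np.random.default_rng(spec.seed)
    sense_ids = np.array([CODON_INDEX[c] for c in code.sense_codons])
    if isinstance(spec.codon_frequencies, str):
        freqs = np.full(len(sense_ids), 1.0 / len(sense_ids))
    else:
        freqs = np.asarray(spec.codon_frequencies, dtype=float)

    lo, hi = spec.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)
    ancestor = [rng.choice(sense_ids, size=int(n), p=freqs) for n in lengths]
    locked = [np.zeros(int(n), dtype=bool) for n in lengths]

    # ---- plant pair occurrences (non-overlapping) ----------------------
    slot_counts = lengths - 1
    cum_slots = np.cumsum(slot_counts)
    total_slots = int(cum_slots[-1])
    occupied: set[tuple[int, int]] = set()
    occurrences: list[dict] = []
    for planted in spec.planted_pairs:
        id1, id2 = CODON_INDEX[planted.pair[0]], CODON_INDEX[planted.pair[1]]
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < planted.occurrences:
            attempts += 1
            if attempts > 1000 * max(planted.occurrences, 1):
                raise SimulationError(
                    f"cannot place {planted.occurrences} occurrences of "
                    f"{pair_label(*planted.pair)}: genome capacity exhausted")
            r = int(rng.integers(total_slots))
            g = int(np.searchsorted(cum_slots, r, side="right"))
            idx = r - (int(cum_slots[g - 1]) if g else 0)
            if (g, idx) in occupied or (g, idx + 1) in occupied \
                    or (g, idx - 1) in occupied:
                continue
            ancestor[g][idx] = id1
            ancestor[g][idx + 1] = id2
            occupied.add((g, idx))
            occupied.add((g, idx + 1))
            placed.append((g, idx))
        n_lock = int(round(planted.lock_fraction * len(placed)))
        lock_idx = set(rng.permutation(len(placed))[:n_lock].tolist())
        for j, (g, idx) in enumerate(placed):
            is_locked = j in lock_idx
            if is_locked:
                locked[g][idx] = True
                locked[g][idx + 1] = True
            occurrences.append({
                "orf_id": f"{spec.reference}_{g:04d}",
                "pair": pair_label(*planted.pair),
                "start_codon_index": idx + 1,
                "locked": is_locked,
            })

    # ---- derive species ------------------------------------------------
    partners = synonymous_partners(spec.code_table)
    syn_mat, syn_counts = _ragged({
        CODON_INDEX[c]: [CODON_INDEX[p] for p in alts]
        for c, alts in partners.items()
    })
    nonsyn_lists = {
        CODON_INDEX[c]: [
            CODON_INDEX[d] for d in code.sense_codons
            if code.amino_acid(d) != code.amino_acid(c)
        ]
        for c in code.sense_codons
    }
    ns_mat, ns_counts = _ragged(nonsyn_lists)

    genes: dict[str, list[np.ndarray]] = {spec.reference: ancestor}
    for sp in spec.species_ids[1:]:
        derived: list[np.ndarray] = []
        for g in range(spec.n_genes):
            ids = ancestor[g]
            lock = locked[g]
            n = len(ids)
            sub_mask = (rng.random(n) < spec.substitution_prob) & ~lock
            out = _mutate(ids, sub_mask, syn_mat, syn_counts, rng)
            if spec.nonsynonymous_prob > 0:
                ns_mask = (rng.random(n) < spec.nonsynonymous_prob) \
                    & ~lock & ~sub_mask
                out = _mutate(out, ns_mask, ns_mat, ns_counts, rng)
            if spec.indel_prob > 0:
                events = rng.random(n) < spec.indel_prob
                deletions = rng.random(n) < 0.5
                inserts = rng.choice(sense_ids, size=n, p=freqs)
                pieces: list[int] = []
                for i in range(n):
                    near_lock = lock[i] or (i + 1 < n and lock[i + 1])
                    if events[i] and not near_lock:
                        if deletions[i]:
                            continue
                        pieces.append(int(out[i]))
                        pieces.append(int(inserts[i]))
                    else:
                        pieces.append(int(out[i]))
                out = np.array(pieces, dtype=np.int64)
            derived.append(out)
        genes[sp] = derived

    # ---- ground truth --------------------------------------------------
    orf_conserved = None
    realized = None
    if spec.indel_prob == 0:
        orf_conserved = {}
        conserved_flags: list[np.ndarray] = []
        for g in range(spec.n_genes):
            flags = np.ones(len(ancestor[g]), dtype=bool)
            for sp in spec.species_ids[1:]:
                flags &= genes[sp][g] == ancestor[g]
            conserved_flags.append(flags)
            orf_conserved[f"{spec.reference}_{g:04d}"] = (
                int(len(flags)), int(flags.sum()))
        realized = {}
        for planted in spec.planted_pairs:
            id1, id2 = (CODON_INDEX[planted.pair[0]],
                        CODON_INDEX[planted.pair[1]])
            total = conserved = 0
            for g in range(spec.n_genes):
                ids = ancestor[g]
                hits = np.nonzero((ids[:-1] == id1) & (ids[1:] == id2))[0]
                total += len(hits)
                flags = conserved_flags[g]
                conserved += int(np.sum(flags[hits] & flags[hits + 1]))
            realized[pair_label(*planted.pair)] = {
                "total": total, "conserved": conserved}

    truth = TruthRecord(
        planted_occurrences=occurrences,
        orf_conserved=orf_conserved,
        realized_planted=realized,
        neutral_coupling=1.0,
    )
    return SyntheticDataset(spec=spec, genes=genes, truth=truth)


def to_alignments(
    dataset: SyntheticDataset, code: GeneticCode | None = None
) -> list[CodonAlignment]:
    """Codon alignments for a generated dataset.

    Without indels every species has the gene's ancestral codon length and
    the alignment is gap-free by construction, so rows are materialized
    directly; with indels each orthogroup goes through the full
    translate–align–backtranslate path.
    """
    spec = dataset.spec
    code = code or load_genetic_code(spec.code_table)
    if spec.indel_prob == 0:
        out = []
        for i in range(spec.n_genes):
            rows = {
                sp: tuple(_CODON_ARR[dataset.genes[sp][i]])
                for sp in spec.species_ids
            }
            out.append(CodonAlignment(
                group_id=dataset.orf_id(spec.reference, i),
                reference=spec.reference, rows=rows))
        return out
    return [
        align_group(group, code, reference=spec.reference)
        for group in dataset.groups()
    ]


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Emit per-species FASTA, the ortholog TSV and the truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in dataset.spec.species_ids:
        write_fasta(dataset.sequences(sp), outdir / f"{sp}.fasta")
    with (outdir / "orthologs.tsv").open("w") as handle:
        for row in dataset.ortholog_rows():
            handle.write("\t".join(row) + "\n")
    dataset.truth.to_json(outdir / "truth.json")


DEFAULT_CATEGORY_PROBS = (0.12, 0.18, 0.35, 0.25, 0.10)


def emit_property_table(
    dataset: SyntheticDataset,
    focal_orfs: frozenset[str] | None = None,
    control_orfs: frozenset[str] = frozenset(),
    shifts: Mapping[str, Mapping[str, object]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-gene property table with optional set-wise shifts.

    Numeric properties get a lognormal baseline; ``shifts`` maps a set name
    (``"focal"`` / ``"control"``) to multiplicative factors per numeric
    property and/or a ``"polysome_probs"`` vector over the five categories.
    ``focal_orfs`` defaults to ORFs carrying a locked planted occurrence.
    Deterministic per seed.
    """
    spec = dataset.spec
    if focal_orfs is None:
        focal_orfs = dataset.truth.focal_orfs()
    shifts = shifts or {}
    rng = np.random.default_rng(seed)
    ids = [dataset.orf_id(spec.reference, i) for i in range(spec.n_genes)]
    lengths = np.array([len(g) for g in dataset.genes[spec.reference]])
    n = spec.n_genes
    table = pd.DataFrame({
        "orf_id": ids,
        "cai": np.clip(rng.lognormal(np.log(0.15), 0.35, n), 0.01, 0.99),
        "length_codons": lengths.astype(float),
        "protein_abundance": rng.lognormal(np.log(2000.0), 1.2, n),
        "mrna_half_life": rng.lognormal(np.log(8.0), 0.5, n),
    })
    membership = np.array([
        "focal" if i in focal_orfs else
        "control" if i in control_orfs else "other"
        for i in ids
    ])
    for set_name, shift in shifts.items():
        sel = membership == set_name
        for prop, factor in shift.items():
            if prop == "polysome_probs":
                continue
            table.loc[sel, prop] = table.loc[sel, prop] * float(factor)
    cats = np.empty(n, dtype=object)
    for set_name in ("focal", "control", "other"):
        sel = membership == set_name
        probs = shifts.get(set_name, {}).get(
            "polysome_probs", DEFAULT_CATEGORY_PROBS)
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum()
        cats[sel] = rng.choice(POLYSOME_CATEGORIES, size=int(sel.sum()),
                               p=probs)
    table["polysome_category"] = cats
    return table
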