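"""Reference-anchored residue mapping and bicarbonate-site genotyping.

Sperm-specific soluble adenylyl cyclase (sAC) binds bicarbonate through two
positively charged residues of the human enzyme, K95 and R176.  This module
aligns curated ortholog protein sequences to a human reference, maps the
reference coordinates through the alignment, and classifies each ortholog's
"genotype" — the pair of residues at the positions homologous to K95/R176,
written ``"X/Y"`` — together with conservation checks of the two
catalytic-loop motifs (AGD, FDKG).

Alignment is global with affine gap penalties (Needleman-Wunsch-Gotoh via
``Bio.Align.PairwiseAligner``), BLOSUM62 by default with 'X' neutralised to
score zero against everything.  Coordinates are 1-based throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
POSITIVE_RESIDUES = frozenset("KRH")
GAP = "-"


class InputError(ValueError):
    """Invalid input data (empty sequence, bad position, duplicate id...)."""


class ConfigError(ValueError):
    """Invalid configuration (unknown matrix name, bad gap penalties...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with free-text clade metadata.

    ``residues`` is an uppercase amino-acid string; positions are 1-based
    and contiguous.  'X' is allowed as an unknown residue.
    """

    id: str
    species: str = ""
    group: str = ""
    residues: str = ""

    def __post_init__(self):
        if not self.residues:
            raise InputError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - AMINO_ACIDS - {"X"}
        if bad:
            raise InputError(
                f"record {self.id!r}: invalid residues {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentParams:
    """Global affine-gap alignment parameters.

    Gap of length L costs ``gap_open + (L - 1) * gap_extend`` (both
    negative, opening at least as costly as extending).
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend < 0):
            raise ConfigError(
                f"require gap_open <= gap_extend < 0, got "
                f"{self.gap_open}/{self.gap_extend}"
            )


@dataclass
class PairwiseAlignment:
    """A scored global alignment of reference ``a`` against query ``b``."""

    a_id: str
    b_id: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise InputError("gapped strings differ in length")
        # 1-based ref position -> 1-based query position (or None at a gap)
        self.a_to_b: dict[int, int | None] = {}
        pa = pb = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != GAP:
                pa += 1
            if cb != GAP:
                pb += 1
            if ca != GAP:
                self.a_to_b[pa] = pb if cb != GAP else None

    @property
    def ungapped_a(self) -> str:
        return self.aligned_a.replace(GAP, "")

    @property
    def ungapped_b(self) -> str:
        return self.aligned_b.replace(GAP, "")


@dataclass
class SiteMap:
    """Named reference sites and loop motifs, reference numbering."""

    reference_id: str
    sites: dict[str, int]
    loops: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    bicarbonate_sites: tuple[str, str] = ("K95", "R176")

    def __post_init__(self):
        positions = list(self.sites.values())
        if len(set(positions)) != len(positions):
            raise InputError("duplicate reference positions in site map")
        for name, (start, end, motif) in self.loops.items():
            if end - start + 1 != len(motif):
                raise InputError(f"loop {name!r}: range does not match motif")


@dataclass(frozen=True)
class GenotypeCall:
    """Residues at the positions homologous to K95/R176, as "X/Y"."""

    residue_at_k95: str
    residue_at_r176: str

    @property
    def label(self) -> str:
        return f"{self.residue_at_k95}/{self.residue_at_r176}"

    @property
    def charge_class(self) -> str:
        n = sum(r in POSITIVE_RESIDUES
                for r in (self.residue_at_k95, self.residue_at_r176))
        return {2: "both-positive", 1: "one-positive", 0: "none-positive"}[n]


@dataclass
class SurveyTable:
    """Per-species genotype rows plus per-group aggregates."""

    rows: pd.DataFrame
    aggregates: pd.DataFrame


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _build_aligner(params: AlignmentParams) -> PairwiseAligner:
    try:
        matrix = substitution_matrices.load(params.substitution_matrix)
    except FileNotFoundError as exc:
        raise ConfigError(
            f"unknown substitution matrix {params.substitution_matrix!r}"
        ) from exc
    matrix = matrix.copy()
    if "X" in matrix.alphabet:
        # 'X' is an unknown residue: neutral, scores 0 against everything.
        for aa in matrix.alphabet:
            matrix["X", aa] = 0.0
            matrix[aa, "X"] = 0.0
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def align_global(
    a: ProteinRecord, b: ProteinRecord,
    params: AlignmentParams | None = None,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of reference ``a`` vs query ``b``.

    Deterministic: of the co-optimal alignments the first in biopython's
    fixed traceback order is returned.
    """
    params = params or AlignmentParams()
    aligner = _build_aligner(params)
    aln = aligner.align(a.residues, b.residues)[0]
    return PairwiseAlignment(
        a_id=a.id, b_id=b.id,
        aligned_a=str(aln[0]), aligned_b=str(aln[1]),
        score=float(aln.score),
    )


def percent_identity(
    aln: PairwiseAlignment, denominator: str = "aligned_columns"
) -> float:
    """100 x identical columns / denominator.

    Policies: ``aligned_columns`` (default; columns between the first and
    last column where both sequences have a residue, i.e. terminal gap runs
    excluded), ``alignment_length`` (all columns), ``ungapped_columns``
    (columns where both have a residue).  'X' never counts as an identity.
    """
    cols = list(zip(aln.aligned_a, aln.aligned_b))
    both = [i for i, (x, y) in enumerate(cols) if x != GAP and y != GAP]
    if not both:
        raise InputError("alignment has no aligned residue pair")
    identities = sum(
        1 for x, y in cols if x == y and x != GAP and x != "X"
    )
    if denominator == "aligned_columns":
        denom = both[-1] - both[0] + 1
    elif denominator == "alignment_length":
        denom = len(cols)
    elif denominator == "ungapped_columns":
        denom = len(both)
    else:
        raise ConfigError(f"unknown denominator policy {denominator!r}")
    if denom == 0:
        raise InputError("zero-length denominator")
    return 100.0 * identities / denom


def map_site(aln: PairwiseAlignment, ref_pos: int) -> int | None:
    """Query position aligned to reference position, or None at a gap."""
    n_ref = len(aln.ungapped_a)
    if not 1 <= ref_pos <= n_ref:
        raise InputError(f"reference position {ref_pos} outside 1..{n_ref}")
    return aln.a_to_b[ref_pos]


# ---------------------------------------------------------------------------
# Genotyping
# ---------------------------------------------------------------------------

def _residue_at(query: ProteinRecord, aln: PairwiseAlignment,
                ref_pos: int) -> str:
    qpos = map_site(aln, ref_pos)
    return GAP if qpos is None else query.residues[qpos - 1]


def call_genotype(
    query: ProteinRecord, aln: PairwiseAlignment, sites: SiteMap,
) -> GenotypeCall:
    """Genotype label from the residues homologous to K95 and R176.

    An unmapped site (reference position opposite a gap) yields ``-`` in
    the label and counts as non-positive.
    """
    if aln.b_id != query.id:
        raise InputError("alignment query id does not match record")
    k_site, r_site = sites.bicarbonate_sites
    return GenotypeCall(
        residue_at_k95=_residue_at(query, aln, sites.sites[k_site]),
        residue_at_r176=_residue_at(query, aln, sites.sites[r_site]),
    )


def check_motifs(
    query: ProteinRecord, aln: PairwiseAlignment, sites: SiteMap,
) -> dict[str, dict]:
    """Map each loop range into the query and compare against its motif.

    Returns per loop: the mapped query range (or None), the query
    substring, and a boolean match.
    """
    report: dict[str, dict] = {}
    for name, (start, end, motif) in sites.loops.items():
        qpos = [map_site(aln, p) for p in range(start, end + 1)]
        if any(p is None for p in qpos):
            report[name] = {"range": None, "observed": None, "match": False}
            continue
        observed = query.residues[qpos[0] - 1: qpos[-1]]
        report[name] = {
            "range": (qpos[0], qpos[-1]),
            "observed": observed,
            "match": observed == motif,
        }
    return report


def survey(
    records: Sequence[ProteinRecord],
    reference: ProteinRecord,
    sites: SiteMap,
    params: AlignmentParams | None = None,
    absent_species: Sequence[tuple[str, str]] = (),
) -> SurveyTable:
    """Genotype every record against the reference and aggregate by group.

    ``absent_species`` lists (species, group) pairs known to lack a sAC
    gene; they enter the table with ``has_sac=False`` and no genotype, so
    presence fractions (e.g. 11 of 13 searchable species) can be computed
    from curated counts.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate record ids")
    if any(r.id == reference.id for r in records):
        raise InputError("reference must be distinct from queries")

    rows = []
    for rec in records:
        aln = align_global(reference, rec, params)
        geno = call_genotype(rec, aln, sites)
        motifs = check_motifs(rec, aln, sites)
        rows.append({
            "id": rec.id, "species": rec.species, "group": rec.group,
            "has_sac": True,
            "genotype": geno.label, "charge_class": geno.charge_class,
            "identity_pct": percent_identity(aln),
            **{f"motif_{name}": rep["match"] for name, rep in motifs.items()},
        })
    for species, group in absent_species:
        rows.append({
            "id": "", "species": species, "group": group,
            "has_sac": False, "genotype": "", "charge_class": "",
            "identity_pct": float("nan"),
        })
    columns = ["id", "species", "group", "has_sac", "genotype",
               "charge_class", "identity_pct"]
    columns += [f"motif_{name}" for name in sites.loops]
    table = pd.DataFrame(rows, columns=columns)

    if table.empty:
        agg = pd.DataFrame(
            columns=["group", "n", "n_with_sac", "fraction_with_sac",
                     "genotype", "n_genotype", "fraction_genotype"])
    else:
        parts = []
        for group, sub in table.groupby("group", sort=True):
            n = len(sub)
            with_sac = sub[sub["has_sac"]]
            if len(with_sac):
                counts = with_sac["genotype"].value_counts()
            else:
                counts = pd.Series(dtype=int)
            base = {"group": group, "n": n, "n_with_sac": len(with_sac),
                    "fraction_with_sac": len(with_sac) / n}
            if counts.empty:
                parts.append({**base, "genotype": "", "n_genotype": 0,
                              "fraction_genotype": float("nan")})
            else:
                for label, cnt in counts.items():
                    parts.append({**base, "genotype": label,
                                  "n_genotype": int(cnt),
                                  "fraction_genotype": cnt / len(with_sac)})
        agg = pd.DataFrame(parts)
    return SurveyTable(rows=table, aggregates=agg)


# ---------------------------------------------------------------------------
# Tree annotation and I/O
# ---------------------------------------------------------------------------

def annotate_tree(
    newick: str, table: SurveyTable,
) -> tuple[dendropy.Tree, list[str]]:
    """Attach genotype/presence annotations to matching tree leaves.

    Leaf taxon labels are matched exactly against the table's species
    column.  Returns the annotated tree and the list of unmatched leaf
    labels.
    """
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise InputError(f"malformed newick: {exc}") from exc
    by_species = {
        row["species"]: row for _, row in table.rows.iterrows()
    }
    unmatched = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else ""
        row = by_species.get(label)
        if row is None:
            unmatched.append(label)
            continue
        leaf.annotations.add_new("has_sac", str(bool(row["has_sac"])))
        leaf.annotations.add_new("genotype", str(row["genotype"]))
        leaf.annotations.add_new("charge_class", str(row["charge_class"]))
    return tree, unmatched


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein FASTA; description parsed as ``id species=... group=...``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:]
            if "=" in tok
        )
        records.append(ProteinRecord(
            id=rec.id,
            species=meta.get("species", "").replace("_", " "),
            group=meta.get("group", ""),
            residues=str(rec.seq).upper(),
        ))
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            species = rec.species.replace(" ", "_")
            fh.write(f">{rec.id} species={species} group={rec.group}\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Brute-force alignment scoring (shared by the test oracle and CLI checks)
# ---------------------------------------------------------------------------

def score_alignment(
    aligned_a: str, aligned_b: str, params: AlignmentParams | None = None,
) -> float:
    """Re-score a gapped alignment under the affine-gap model."""
    params = params or AlignmentParams()
    matrix = substitution_matrices.load(params.substitution_matrix)
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == GAP and cb == GAP:
            raise InputError("double-gap column")
        if ca == GAP:
            score += params.gap_extend if in_gap_a else params.gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == GAP:
            score += params.gap_extend if in_gap_b else params.gap_open
            in_gap_a, in_gap_b = False, True
        else:
            if "X" in (ca, cb):
                pair = 0.0
            else:
                pair = float(matrix[ca, cb])
            score += pair
            in_gap_a = in_gap_b = False
    return score
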