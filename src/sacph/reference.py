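"""Packaged human-sAC-like reference and its functional site map.

The real human sAC protein cannot be redistributed here, so the packaged
reference is a *synthetic* 469-residue sequence with the documented
functional-site architecture planted at the canonical human coordinates:
the two bicarbonate-coordinating residues K95 and R176, the catalytic
residues (D47, D99, K144, K334, N412, R416), and the two catalytic-loop
motifs AGD (97-99) and FDKG (338-341).  All coordinate conventions in the
package are 1-based and inclusive, in this truncated-isoform numbering.

Everything downstream (alignment, site mapping, genotyping, the synthetic
ortholog generator) treats this sequence exactly as it would treat the real
reference; only the background residues between the planted sites are
random.
"""

from __future__ import annotations

from sacph.orthosite import ProteinRecord, SiteMap

# Synthetic reference sequence (fixed; background drawn once from a seeded
# RNG, functional sites planted at human-sAC coordinates).
HUMAN_SAC_REFERENCE_SEQ = (
    "WQACRGHRMNIMQYIPCFWFNGCHTLVEVVNNNRTWSTAGYVWGKEDDRHITFKMAESSAYWRPPTRFTT"
    "SCTRLMISGNICSYNCKDMAAGWKKFAGDSVPPTKARYFFQQYCPGVPGGEDRMSAADYTNQVFFHPHKL"
    "VTSKLDPIAWSPFRICHQDMKSPWLDRWMWLCGRVRSYKWKAVGERQDSPRCLQEYKHARNDIRYLIHSH"
    "LFAMFQFEHSERPNDHCAWLNEHRHFLNFWERKSCRHRNNGATQVEWIDIETHPAVVYEQCARFKYQSNQ"
    "PTQFPAWWRHCTRHEQRMWWRLNDGKAGPYCRETNQIATQRLHHGPEWVKEVTKHLCFDKGLWTPGIMLP"
    "PQEQGRLVRNPLNFIYKWNKMWIPSNAMWHANMETNVWQTYPVIMSNRYAHHNDNAYLQCENRWDRYLED"
    "IPDKNQNECMYVKWRAIEQWHKNWPCNASVCKVSYHNAELNPTPVYTHY"
)

REFERENCE_ID = "HsSAC_t_synthetic"


def human_sac_reference() -> ProteinRecord:
    """The packaged (synthetic) human sAC_t reference record."""
    return ProteinRecord(
        id=REFERENCE_ID,
        species="Homo sapiens (synthetic analogue)",
        group="mammals",
        residues=HUMAN_SAC_REFERENCE_SEQ,
    )


def human_site_map() -> SiteMap:
    """Functional sites of the reference, human-sAC_t numbering.

    ``K95`` and ``R176`` are the bicarbonate-coordinating residues whose
    homologous positions define the "X/Y" genotype; the two loop motifs
    (AGD, FDKG) flank the catalytic centre and serve as conservation
    controls.
    """
    return SiteMap(
        reference_id=REFERENCE_ID,
        sites={
            "D47": 47,
            "K95": 95,
            "D99": 99,
            "K144": 144,
            "R176": 176,
            "K334": 334,
            "N412": 412,
            "R416": 416,
        },
        loops={
            "C1-b2/3": (97, 99, "AGD"),
            "C2-b2/3": (338, 341, "FDKG"),
        },
        bicarbonate_sites=("K95", "R176"),
    )
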