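"""Packaged gene signatures.

Two signatures ship with the package:

* the 20-gene HSC Aging Signature — the genes most consistently reported
  as differentially expressed between aged and young murine LT-HSCs;
* the 16-gene Haem p53Score set — validated Trp53 transcriptional targets
  whose upregulation under genotoxic stress is rescued by Trp53 loss in
  multiple HSPC subtypes, used to quantify p53 transcriptional activity
  in both mouse and human haematopoietic cells.

Symbols are mouse gene symbols; :func:`to_human_symbols` maps them onto
human nomenclature (uppercasing plus an override table for the known
divergent names).
"""

from __future__ import annotations

from .datatypes import GeneSignature

__all__ = [
    "AGING_SIGNATURE_GENES",
    "HAEM_P53_GENES",
    "aging_signature",
    "haem_p53_signature",
    "to_human_symbols",
]

AGING_SIGNATURE_GENES: tuple[str, ...] = (
    "Selp", "Mt1", "Nupr1", "Plscr2", "Clec1a", "Gstm2", "Enpp5", "Itgb3",
    "Mt2", "Clca3a1", "Zg16", "Sbspon", "Trpc1", "Gpr183", "Klhl4", "Ptprk",
    "Vwf", "Cd38", "Neo1", "Fhl1",
)

HAEM_P53_GENES: tuple[str, ...] = (
    "Cdkn1a", "Eda2r", "Phlda3", "Bax", "Zmat3", "Pvt1", "Sulf2", "Ccng1",
    "Bbc3", "Perp", "Casp1", "Aen", "Tnfrsf10b", "Ctsd", "Ier5", "Pml",
)

# Mouse -> human symbol divergences that plain uppercasing does not cover.
_MOUSE_HUMAN_OVERRIDES: dict[str, str] = {
    "Trp53": "TP53",
    "Trp53inp1": "TP53INP1",
    "Mt1": "MT1A",
    "Mt2": "MT2A",
}


def to_human_symbols(genes: tuple[str, ...] | list[str]) -> tuple[str, ...]:
    """Map mouse gene symbols to human symbols (uppercase + overrides)."""
    return tuple(_MOUSE_HUMAN_OVERRIDES.get(g, g.upper()) for g in genes)


def aging_signature(reference_pool: tuple[str, ...] | None = None) -> GeneSignature:
    """The 20-gene HSC Aging Signature."""
    return GeneSignature(
        name="aging_signature",
        genes=AGING_SIGNATURE_GENES,
        reference_pool=reference_pool,
        notes="20 genes upregulated with murine LT-HSC age",
    )


def haem_p53_signature(
    reference_pool: tuple[str, ...] | None = None, species: str = "mouse"
) -> GeneSignature:
    """The 16-gene Haem p53Score signature.

    Parameters
    ----------
    reference_pool
        Optional fixed control-gene pool (e.g. a curated ~694-gene reference
        list supplied as a config slot); when omitted, expression-matched
        controls are sampled at scoring time.
    species
        ``"mouse"`` (native symbols) or ``"human"`` (case-normalized
        mapping applied).
    """
    genes = HAEM_P53_GENES
    pool = reference_pool
    if species == "human":
        genes = to_human_symbols(genes)
        if pool is not None:
            pool = to_human_symbols(pool)
    elif species != "mouse":
        raise ValueError(f"unknown species {species!r}")
    return GeneSignature(
        name="haem_p53_score",
        genes=genes,
        reference_pool=pool,
        notes="16 p53 target genes with p53-dependent expression in HSPCs",
    )
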