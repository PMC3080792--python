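"""Loaders for the small reference datasets packaged with the library."""

from __future__ import annotations

from importlib import resources

from membranome.quant import ProteinQuantRecord, read_quant_tsv


def _load(name: str) -> list[ProteinQuantRecord]:
    text = resources.files("membranome").joinpath("data", name).read_text(encoding="utf-8")
    return read_quant_tsv(text)


def load_translation_factors() -> list[ProteinQuantRecord]:
    """Translation initiation/elongation factors with P/H ratios (28 records)."""
    return _load("translation_factors.tsv")


def load_neuron_restricted() -> list[ProteinQuantRecord]:
    """Primarily neuron-associated proteins detected in the membranome (14 records)."""
    return _load("neuron_restricted.tsv")


def load_dna_packaging() -> list[ProteinQuantRecord]:
    """DNA-packaging-annotated proteins with subcellular specificity (8 records)."""
    return _load("dna_packaging.tsv")
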