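"""Access to configuration files shipped with the package."""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def _data_path(name: str) -> Path:
    return Path(str(resources.files("cohortsim").joinpath("data", name)))


def default_label_scheme():
    from .labels import LabelScheme

    return LabelScheme.from_file(_data_path("mesh_c_labels.txt"))


def default_cue_lexicon(scope_window: int = 5):
    from .text import read_cue_lexicon

    return read_cue_lexicon(_data_path("default_cues.tsv"), scope_window=scope_window)


def default_phenotype_routing() -> dict[str, frozenset[str]]:
    """Phenotype -> label-subset routing used for cohort retrieval.

    Osteoporosis is compared on the musculoskeletal and nutritional
    labels, nephritis in lupus on urogenital and immune, interstitial
    lung disease in systemic sclerosis on respiratory and immune, and
    lung infection on respiratory and infections.
    """
    from .retrieval import read_routing_tsv

    return read_routing_tsv(_data_path("routing.tsv"))


def golden_expected_dir() -> Path:
    """Directory of frozen expected outputs for the packaged miniature corpus."""
    return _data_path("golden")
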