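"""Packaged fixtures: the DDR PTM pair table and a 12-species test tree.

``load_ddr_ptm_pairs`` returns the published table of 99 target-modifier
pairs of the human DNA damage response, with ages as short group labels.
``load_fixture_tree`` returns a small ladder-shaped species tree with one
representative per age group (plus a second early eukaryote) whose groups
are monophyletic, convenient for exercising every pipeline stage.
"""

from __future__ import annotations

from importlib import resources

from .core import DEFAULT_SCALE, AgeScale, SpeciesTree, parse_species_tree, read_group_map
from .ptm import PTMNetwork, load_ptm_pairs


def _data(name: str):
    return resources.files("netage.data").joinpath(name)


def load_ddr_ptm_pairs(scale: AgeScale = DEFAULT_SCALE) -> PTMNetwork:
    """The DDR target-modifier pair table (99 rows incl. self-pairs)."""
    with resources.as_file(_data("ddr_ptm_pairs.tsv")) as path:
        return load_ptm_pairs(path, scale=scale)


def load_fixture_tree(scale: AgeScale = DEFAULT_SCALE) -> SpeciesTree:
    """12-leaf species tree, one leaf per age group (two early eukaryotes)."""
    newick = _data("fixture_tree.nwk").read_text()
    with resources.as_file(_data("fixture_groups.tsv")) as path:
        groups, complete = read_group_map(path)
    return parse_species_tree(newick, groups, scale=scale, complete=complete)
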