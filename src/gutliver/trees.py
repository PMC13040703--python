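"""Rooted phylogenetic tree input for UniFrac distances."""

from __future__ import annotations

import logging
from pathlib import Path

from skbio import TreeNode

log = logging.getLogger(__name__)


def read_newick(path: str | Path) -> TreeNode:
    """Read a rooted tree from a newick file.

    Branch lengths default to 0 (with a warning) when the string carries
    none; negative branch lengths are rejected.  Parse errors (for example
    unbalanced parentheses) propagate from the newick parser.
    """
    tree = TreeNode.read(str(path), format="newick")
    missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            missing += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length {node.length} in {path}")
    if missing:
        log.warning("%s: %d branches without lengths, defaulted to 0", path, missing)
    leaves = [t.name for t in tree.tips()]
    if len(leaves) != len(set(leaves)):
        raise ValueError(f"{path}: duplicate leaf names")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
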