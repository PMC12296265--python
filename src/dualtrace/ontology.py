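"""Hierarchical region ontology (acronym tree).

A miniature stand-in for an atlas ontology: each node has an acronym, a
human-readable name, and children. Exclusion rules and always-omitted
structures (fiber tracts, ventricles) are resolved against this tree.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path


class UnknownAcronymError(KeyError):
    """Raised for an acronym absent from the ontology; carries suggestions."""

    def __init__(self, acronym: str, suggestions: list[str]):
        self.acronym = acronym
        self.suggestions = suggestions
        hint = f"; did you mean {suggestions}?" if suggestions else ""
        super().__init__(f"unknown region acronym {acronym!r}{hint}")


@dataclass
class RegionNode:
    acronym: str
    name: str = ""
    children: list["RegionNode"] = field(default_factory=list)


class Ontology:
    """Acronym-keyed region tree with descendant and ancestor queries."""

    def __init__(self, root: RegionNode):
        self.root = root
        self._nodes: dict[str, RegionNode] = {}
        self._parent: dict[str, str | None] = {root.acronym: None}
        stack = [root]
        while stack:
            node = stack.pop()
            if node.acronym in self._nodes:
                raise ValueError(f"duplicate acronym {node.acronym!r} in ontology")
            self._nodes[node.acronym] = node
            for child in node.children:
                self._parent[child.acronym] = node.acronym
                stack.append(child)

    def __contains__(self, acronym: str) -> bool:
        return acronym in self._nodes

    @property
    def acronyms(self) -> list[str]:
        return list(self._nodes)

    def validate(self, acronym: str) -> str:
        if acronym not in self._nodes:
            raise UnknownAcronymError(
                acronym, difflib.get_close_matches(acronym, self._nodes, n=3)
            )
        return acronym

    def parent(self, acronym: str) -> str | None:
        self.validate(acronym)
        return self._parent[acronym]

    def descendants(self, acronym: str, include_self: bool = True) -> set[str]:
        """All acronyms in the subtree rooted at ``acronym``."""
        self.validate(acronym)
        out: set[str] = set()
        stack = [self._nodes[acronym]]
        while stack:
            node = stack.pop()
            out.add(node.acronym)
            stack.extend(node.children)
        if not include_self:
            out.discard(acronym)
        return out

    # ---- JSON round trip: {"acronym": ..., "name": ..., "children": [...]}

    @classmethod
    def from_json(cls, path: str | Path) -> "Ontology":
        with open(path) as fh:
            data = json.load(fh)
        return cls(_node_from_dict(data))

    @classmethod
    def from_dict(cls, data: dict) -> "Ontology":
        return cls(_node_from_dict(data))

    def to_dict(self) -> dict:
        return _node_to_dict(self.root)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _node_from_dict(d: dict) -> RegionNode:
    return RegionNode(
        acronym=d["acronym"],
        name=d.get("name", ""),
        children=[_node_from_dict(c) for c in d.get("children", [])],
    )


def _node_to_dict(n: RegionNode) -> dict:
    return {
        "acronym": n.acronym,
        "name": n.name,
        "children": [_node_to_dict(c) for c in n.children],
    }
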