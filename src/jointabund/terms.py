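"""Model-term utilities: canonical names, components, hierarchy expansion.

A term is a covariate name or a colon-joined interaction of covariate names
("harvested_cropland_pct:year"). Canonical form sorts components
alphabetically so equivalent spellings compare equal. ``year`` is an
ordinary component here; its centering is handled by the design builder.
"""

from __future__ import annotations

from itertools import combinations


def components(term: str) -> tuple:
    return tuple(term.split(":"))


def canonical(term: str) -> str:
    return ":".join(sorted(components(term)))


def order(term: str) -> int:
    return len(components(term))


def hierarchy(term: str) -> set:
    """All lower-and-equal-order terms implied by ``term``.

    An interaction brings every main effect and lower-order interaction of
    its components, e.g. a three-way term expands to 3 mains + 3 two-ways +
    itself.
    """
    comps = components(term)
    out = set()
    for k in range(1, len(comps) + 1):
        for sub in combinations(sorted(comps), k):
            out.add(":".join(sub))
    return out


def expand_terms(candidates) -> tuple:
    """Hierarchy-complete, canonical, deduplicated term tuple.

    Ordered by interaction order then name, so mains precede the
    interactions that imply them.
    """
    full = set()
    for t in candidates:
        full |= hierarchy(t)
    return tuple(sorted(full, key=lambda t: (order(t), t)))


def all_components(term_list) -> set:
    out = set()
    for t in term_list:
        out |= set(components(t))
    return out
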