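"""Machine-readable artifact export: ordered heatmap matrices and
Circos-style chord-link tables.

All exports are deterministic — byte-identical across repeated runs on
the same inputs — so downstream figures are reproducible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np

from .association import MASK_KEPT, AssociationMatrix, write_matrix
from .counts import PairCounts

WEIGHT_N_AND = "n_and"
WEIGHT_ASSOCIATION = "association"


def export_heatmap_matrix(
    m: AssociationMatrix, order: list[str], path: str | Path
) -> Path:
    """Write the labeled matrix in dendrogram leaf order.

    The file round-trips losslessly through :func:`aidmap.association.read_matrix`.
    """
    write_matrix(m.reorder(order), path)
    return Path(path)


def _format_weight(value) -> str:
    if float(value).is_integer():
        return str(int(value))
    return np.format_float_positional(float(value), trim="0", unique=True)


def export_chord_links(
    pairs: Iterable[PairCounts],
    m: AssociationMatrix,
    top_n: int,
    path: str | Path,
    weight: str = WEIGHT_N_AND,
) -> Path:
    """Write a Circos-style link table for the top co-cited diseases.

    Diseases are ranked by total singleton citation count; the ``top_n``
    are retained and one link is written per kept (non-floored,
    non-excluded) unordered pair among them. Link width is the raw
    co-citation count ``n_and`` by default — chord width then reads as
    co-citation volume — or the association value. Rows are ordered by
    descending width, then lexicographically, and an empty table is legal.
    """
    if top_n > m.n:
        raise ValueError(f"top_n={top_n} exceeds the {m.n} labels present")
    if weight not in (WEIGHT_N_AND, WEIGHT_ASSOCIATION):
        raise ValueError(f"unknown weight {weight!r}")

    pair_list = [pc for pc in pairs]
    singles: dict[str, int] = {}
    for pc in pair_list:
        singles.setdefault(pc.term_a, pc.n_a)
        singles.setdefault(pc.term_b, pc.n_b)
    missing = [l for l in m.labels if l not in singles]
    if missing:
        raise ValueError(f"no singleton counts for labels {missing}")

    ranked = sorted(m.labels, key=lambda l: (-singles[l], l))
    retained = set(ranked[:top_n])
    n_and = {pc.key: pc.n_and for pc in pair_list}

    links = []
    for i in range(m.n):
        for j in range(i + 1, m.n):
            a, b = m.labels[i], m.labels[j]
            if a not in retained or b not in retained:
                continue
            if m.mask[i, j] != MASK_KEPT:
                continue
            src, tgt = (a, b) if a < b else (b, a)
            w = n_and[(src, tgt)] if weight == WEIGHT_N_AND else m.values[i, j]
            links.append((src, tgt, float(w)))
    links.sort(key=lambda t: (-t[2], t[0], t[1]))

    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\twidth\n")
        for src, tgt, w in links:
            fh.write(f"{src}\t{tgt}\t{_format_weight(w)}\n")
    if not links:
        import logging

        logging.getLogger(__name__).info("chord-link export %s is empty", path)
    return path


def plot_heatmap(
    m: AssociationMatrix, order: list[str], path: str | Path, cmap: str = "Greys"
) -> Path:
    """Optional static heatmap image of the ordered association matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = m.reorder(order)
    fig, ax = plt.subplots(figsize=(max(4, m.n * 0.2),) * 2)
    im = ax.imshow(ordered.values, cmap=cmap, vmin=0, vmax=1)
    ax.set_xticks(range(m.n), ordered.labels, rotation=90, fontsize=5)
    ax.set_yticks(range(m.n), ordered.labels, fontsize=5)
    fig.colorbar(im, ax=ax, label="association")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
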