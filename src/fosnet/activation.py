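"""Per-specimen regional activation tables (c-fos positive-cell counts).

The central container is :class:`ActivationTable`: a specimens x nodes
matrix of nonnegative integer counts, one row per animal, one column per
hemispheric region node, with a treatment label per animal.  Treatments
follow the four-arm conditioning design: paired CS-US with a social (SL)
or asocial (AL) cue, and the matching unpaired controls (SC, AC).

Missing measurements are explicit ``NaN`` entries, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import RegionNode, RegionRegistry, default_registry

__all__ = ["TREATMENTS", "ActivationTable", "read_activation_table", "write_activation_table"]

#: canonical treatment labels: social/asocial x learning(paired)/control(unpaired)
TREATMENTS: tuple[str, ...] = ("SL", "SC", "AL", "AC")

#: minimum specimens per treatment for a correlation estimate
MIN_SPECIMENS = 3


@dataclass
class ActivationTable:
    """Counts of c-fos positive cells per specimen and hemispheric region.

    Parameters
    ----------
    nodes
        Ordered region nodes (the columns).
    specimens
        Ordered ``(specimen_id, treatment)`` pairs (the rows).
    counts
        ``len(specimens) x len(nodes)`` float array; integer-valued where
        observed, ``NaN`` where missing.
    """

    nodes: list[RegionNode]
    specimens: list[tuple[str, str]]
    counts: np.ndarray
    registry: RegionRegistry = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        m, n = self.counts.shape
        if m != len(self.specimens) or n != len(self.nodes):
            raise ValueError("counts shape does not match specimens x nodes")
        if len({s for s, _ in self.specimens}) != m:
            raise ValueError("duplicate specimen ids")
        observed = self.counts[~np.isnan(self.counts)]
        if (observed < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(observed, np.round(observed)):
            raise ValueError("counts must be integer-valued (cell counts)")
        for t, m_t in self.treatment_sizes().items():
            if m_t < MIN_SPECIMENS:
                raise ValueError(
                    f"treatment {t!r} has {m_t} specimens; at least "
                    f"{MIN_SPECIMENS} are required for a correlation estimate"
                )

    # -- accessors -----------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    @property
    def treatments(self) -> list[str]:
        """Treatment labels present, in canonical order."""
        present = {t for _, t in self.specimens}
        return [t for t in TREATMENTS if t in present] + sorted(present - set(TREATMENTS))

    def treatment_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for _, t in self.specimens:
            sizes[t] = sizes.get(t, 0) + 1
        return sizes

    def specimen_indices(self, treatment: str) -> list[int]:
        idx = [i for i, (_, t) in enumerate(self.specimens) if t == treatment]
        if not idx:
            raise KeyError(f"no specimens with treatment {treatment!r}")
        return idx

    def treatment_block(self, treatment: str) -> tuple[np.ndarray, list[RegionNode]]:
        """Counts for one treatment, restricted to fully observed nodes.

        A node is kept only if *every* specimen of the treatment has a
        measurement for it, so all subsample correlation layers share one
        node set.  Returns ``(M x N' array, kept nodes)``.
        """
        rows = self.counts[self.specimen_indices(treatment)]
        keep = ~np.isnan(rows).any(axis=0)
        return rows[:, keep], [n for n, k in zip(self.nodes, keep) if k]

    def to_frame(self) -> pd.DataFrame:
        """Wide-form DataFrame (index specimen_id, columns node_id) plus treatment."""
        df = pd.DataFrame(
            self.counts, index=[s for s, _ in self.specimens], columns=self.node_ids
        )
        df.insert(0, "treatment", [t for _, t in self.specimens])
        df.index.name = "specimen_id"
        return df


def _sep_for(path: Path, dialect: dict) -> str:
    if "sep" in dialect:
        return dialect["sep"]
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_activation_table(
    path,
    dialect: dict | None = None,
    registry: RegionRegistry | None = None,
) -> ActivationTable:
    """Read an activation table from delimited text.

    Two layouts are supported, declared via ``dialect={"form": ...}``:

    ``"long"``
        Columns ``specimen_id, treatment, region, hemisphere, count``; one
        row per measurement.  Pivoted to wide form.
    ``"wide"`` (default)
        Columns ``specimen_id, treatment, <node_id>...`` with node columns
        named ``"<region>_<l|r>"``; one row per specimen.

    Node order in the result is registry order restricted to observed nodes.
    Unknown region codes, duplicate measurements, and negative or
    non-integer counts are errors.
    """
    path = Path(path)
    dialect = dict(dialect or {})
    registry = registry or default_registry()
    sep = _sep_for(path, dialect)
    form = dialect.get("form", "wide")
    df = pd.read_csv(path, sep=sep)

    if form == "long":
        required = {"specimen_id", "treatment", "region", "hemisphere", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long-form file missing columns: {sorted(missing)}")
        nodes_seen: dict[str, RegionNode] = {}
        for _, row in df.iterrows():
            node = registry.make_node(str(row["region"]), str(row["hemisphere"]))
            nodes_seen.setdefault(node.node_id, node)
        df["_node"] = [
            registry.make_node(str(r), str(h)).node_id
            for r, h in zip(df["region"], df["hemisphere"])
        ]
        dup = df.duplicated(subset=["specimen_id", "_node"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate measurement for specimen {first['specimen_id']!r}, "
                f"node {first['_node']!r}"
            )
        wide = df.pivot(index="specimen_id", columns="_node", values="count")
        treat = df.drop_duplicates("specimen_id").set_index("specimen_id")["treatment"]
        wide.insert(0, "treatment", treat.reindex(wide.index))
        df = wide.reset_index()
    else:
        if "specimen_id" not in df.columns or "treatment" not in df.columns:
            raise ValueError("wide-form file must have 'specimen_id' and 'treatment' columns")

    node_cols = [c for c in df.columns if c not in ("specimen_id", "treatment")]
    parsed = {c: registry.parse_node_id(str(c)) for c in node_cols}
    # registry order restricted to observed nodes
    order = {n.node_id: i for i, n in enumerate(registry.all_nodes())}
    node_cols.sort(key=lambda c: order.get(parsed[c].node_id, len(order)))
    nodes = [parsed[c] for c in node_cols]

    counts = df[node_cols].to_numpy(dtype=float)
    specimens = list(zip(df["specimen_id"].astype(str), df["treatment"].astype(str)))
    return ActivationTable(nodes=nodes, specimens=specimens, counts=counts, registry=registry)


def write_activation_table(table: ActivationTable, path) -> None:
    """Write a wide-form CSV/TSV (inverse of the ``"wide"`` reader layout)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = table.to_frame()
    out = df.copy()
    node_cols = [c for c in out.columns if c != "treatment"]
    # keep integer appearance for observed counts
    for c in node_cols:
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else str(int(round(v))))
    out.to_csv(path, sep=sep)
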