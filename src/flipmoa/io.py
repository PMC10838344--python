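"""Readers, writers and validated in-memory containers for every external format.

Formats handled here:

* counts: gene x sample TSV, or MatrixMarket triplet (``.mtx`` plus
  ``<stem>.genes.txt`` / ``<stem>.samples.txt`` sidecars)
* conditions: two-column TSV mapping sample id to condition
* gene sets / regulons: GMT
* drug-profile library: long TSV (profile_id, drug_id, gene, score) plus a
  metadata TSV (profile_id, quality, fda_approved)
* drug-target interactions: TSV (drug_id, target_id, source_db)
* ortholog map: two-column TSV (source_gene, dest_gene)
* networks: GraphML plus a JSON edge-list twin

Every reader validates and returns a typed container; downstream modules
never touch raw files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger(__name__)

#: Allowed condition labels: unperturbed reference, perturbation alone
#: (e.g. receptor overexpression), and perturbation plus candidate drug.
CONDITIONS = ("control", "perturbed", "perturbed_drug")

#: Declared vocabulary of drug-target interaction sources.
TARGET_SOURCE_DBS = (
    "ChEMBL",
    "DGIdb",
    "DrugBank",
    "IUPHAR",
    "KEGG",
    "PharmGKB",
    "DrugCentral",
)


class FormatError(ValueError):
    """A file violated the documented dialect or an invariant of its type."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with condition labels.

    The entry point of the pipeline, downstream of read alignment and
    quantification.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples) int64
    condition: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            bad = np.argwhere(~np.isfinite(self.counts) | (self.counts != np.floor(self.counts)))
            if bad.size:
                g, s = bad[0]
                raise FormatError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}: {self.counts[g, s]}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}: {self.counts[g, s]}"
            )
        for s in self.sample_ids:
            if s not in self.condition:
                raise FormatError(f"sample {s!r} has no condition label")
            if self.condition[s] not in CONDITIONS:
                raise FormatError(
                    f"sample {s!r} has unknown condition {self.condition[s]!r}; "
                    f"allowed: {CONDITIONS}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition[s] == condition]

    def column_indices(self, condition: str) -> np.ndarray:
        return np.array(
            [j for j, s in enumerate(self.sample_ids) if self.condition[s] == condition],
            dtype=int,
        )

    def canonical(self) -> "CountMatrix":
        """Return a copy with genes and samples sorted lexicographically.

        Makes in-memory equality insensitive to input row/column order.
        """
        gi = np.argsort(self.gene_ids)
        si = np.argsort(self.sample_ids)
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in gi],
            sample_ids=[self.sample_ids[j] for j in si],
            counts=self.counts[np.ix_(gi, si)],
            condition=dict(self.condition),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSet:
    description: str
    members: list[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways or TF regulons) with an optional universe."""

    sets: dict[str, GeneSet]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for sid, gs in self.sets.items():
            if not gs.members:
                raise FormatError(f"gene set {sid!r} is empty")
            _check_unique(gs.members, f"member of set {sid}")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id].members

    def restricted(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Drop members outside *universe*; sets emptied by that are removed."""
        uni = set(universe)
        kept = {}
        for sid, gs in self.sets.items():
            mem = [g for g in gs.members if g in uni]
            if mem:
                kept[sid] = GeneSet(gs.description, mem)
        return GeneSetCollection(kept, universe=sorted(uni))


@dataclass
class DrugProfile:
    drug_id: str
    scores: pd.Series  # indexed by gene, aligned to library gene_space
    quality: bool
    fda_approved: bool


@dataclass
class DrugProfileLibrary:
    """A library of per-gene drug treatment signatures.

    Every profile scores every gene of ``gene_space`` exactly once; one drug
    may own several profiles (doses, time points, cell lines).
    """

    profiles: dict[str, DrugProfile]
    gene_space: list[str]

    def __post_init__(self) -> None:
        _check_unique(self.gene_space, "gene_space gene")
        space = pd.Index(self.gene_space)
        for pid, prof in self.profiles.items():
            if len(prof.scores) != len(space) or not prof.scores.index.equals(space):
                prof_genes = set(prof.scores.index)
                if prof_genes == set(space):
                    prof.scores = prof.scores.reindex(space)
                else:
                    raise FormatError(
                        f"profile {pid!r} does not score the library gene space "
                        f"exactly once ({len(prof.scores)} scores vs "
                        f"{len(space)} genes)"
                    )

    def __len__(self) -> int:
        return len(self.profiles)

    def retained(self) -> "DrugProfileLibrary":
        """Only high-quality profiles of FDA-approved drugs."""
        kept = {
            pid: p for pid, p in self.profiles.items() if p.quality and p.fda_approved
        }
        return DrugProfileLibrary(kept, list(self.gene_space))


@dataclass
class DrugTargetTable:
    """Deduplicated (drug, target, source) interaction rows."""

    rows: pd.DataFrame  # columns drug_id, target_id, source_db
    source_vocabulary: tuple[str, ...] = TARGET_SOURCE_DBS

    def __post_init__(self) -> None:
        need = ["drug_id", "target_id", "source_db"]
        if list(self.rows.columns) != need:
            raise FormatError(f"drug-target table must have columns {need}")
        bad = set(self.rows["source_db"]) - set(self.source_vocabulary)
        if bad:
            raise FormatError(f"unknown source_db values: {sorted(bad)}")
        self.rows = self.rows.drop_duplicates(["drug_id", "target_id"]).reset_index(drop=True)

    def targets_of(self, drug_id: str) -> set[str]:
        return set(self.rows.loc[self.rows["drug_id"] == drug_id, "target_id"])

    def drugs_of(self, target_id: str) -> set[str]:
        return set(self.rows.loc[self.rows["target_id"] == target_id, "drug_id"])


@dataclass
class OrthologMap:
    """One-to-one gene symbol translation (e.g. human -> mouse)."""

    mapping: dict[str, str]
    n_dropped_ambiguous: int = 0

    def __post_init__(self) -> None:
        dests = list(self.mapping.values())
        if len(set(dests)) != len(dests):
            raise FormatError("ortholog map is not one-to-one on destination genes")


# ---------------------------------------------------------------------------
# counts


def read_counts(
    path: str | Path,
    condition_path: str | Path,
    round_fractional: bool = False,
    uppercase: bool = False,
) -> CountMatrix:
    """Read a count matrix (TSV or MatrixMarket triplet) plus conditions.

    Fractional counts are rejected unless ``round_fractional`` is set, in
    which case they are rounded to the nearest integer at read time.
    ``uppercase`` normalizes gene symbols to upper case (human/mouse symbol
    casing differs).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        genes = _read_id_list(path.with_suffix(".genes.txt"))
        samples = _read_id_list(path.with_suffix(".samples.txt"))
        raw = mmread(path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw)
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if pd.Index(df.columns).duplicated().any():
            dup = df.columns[pd.Index(df.columns).duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")

    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        if np.isnan(vals.astype(float)).any():
            g, s = np.argwhere(np.isnan(vals.astype(float)))[0]
            raise FormatError(
                f"NaN count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        frac = vals.astype(float) != np.floor(vals.astype(float))
        if frac.any():
            if round_fractional:
                vals = np.rint(vals.astype(float))
            else:
                g, s = np.argwhere(frac)[0]
                raise FormatError(
                    f"fractional count at gene {df.index[g]!r}, sample "
                    f"{df.columns[s]!r}: {vals[g, s]} (pass round_fractional=True to round)"
                )
        vals = vals.astype(np.int64)

    condition = read_conditions(condition_path)
    missing = [s for s in df.columns if s not in condition]
    if missing:
        raise FormatError(f"samples missing from condition file: {missing}")
    genes = [g.upper() for g in df.index] if uppercase else list(df.index)
    return CountMatrix(
        gene_ids=genes,
        sample_ids=list(df.columns),
        counts=vals,
        condition={s: condition[s] for s in df.columns},
    )


def read_conditions(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{ln}: expected 2 tab-separated fields")
        sid, cond = parts
        if ln == 1 and cond not in CONDITIONS and sid.lower() in {"sample", "sample_id"}:
            continue  # header row
        if cond not in CONDITIONS:
            raise FormatError(
                f"{path}:{ln}: unknown condition {cond!r}; allowed: {CONDITIONS}"
            )
        if sid in out:
            raise FormatError(f"{path}:{ln}: duplicate sample id {sid!r}")
        out[sid] = cond
    return out


def _read_id_list(path: Path) -> list[str]:
    ids = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    _check_unique(ids, f"id in {path.name}")
    return ids


def write_counts(cm: CountMatrix, path: str | Path, condition_path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        mmwrite(path, coo_matrix(cm.counts))
        path.with_suffix(".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        path.with_suffix(".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        cm.to_frame().to_csv(path, sep="\t")
    lines = [f"{s}\t{cm.condition[s]}" for s in cm.sample_ids]
    Path(condition_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in the standard GMT dialect.

    ``set_id TAB description TAB gene TAB gene ...``; duplicate members are
    collapsed, empty sets dropped with a warning.
    """
    sets: dict[str, GeneSet] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: GMT line has fewer than 3 fields")
        sid, desc = parts[0], parts[1]
        if sid in sets:
            raise FormatError(f"{path}:{ln}: duplicate set id {sid!r}")
        members = list(dict.fromkeys(g for g in parts[2:] if g))
        if not members:
            logger.warning("%s:%d: set %r has no members; dropped", path, ln, sid)
            continue
        sets[sid] = GeneSet(desc, members)
    return GeneSetCollection(sets)


def write_gmt(col: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([sid, gs.description or "na", *gs.members])
        for sid, gs in col.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# drug profiles & targets


def read_drug_profiles(path: str | Path, meta_path: str | Path) -> DrugProfileLibrary:
    """Read a long-format profile table plus per-profile metadata.

    The gene space is the union of genes seen in any profile; a profile that
    scores a gene twice or misses one is rejected by name.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"profile_id": str, "drug_id": str, "gene": str, "score": float},
    )
    need = ["profile_id", "drug_id", "gene", "score"]
    if list(df.columns) != need:
        raise FormatError(f"drug profile table must have columns {need}")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"profile_id": str})
    if list(meta.columns) != ["profile_id", "quality", "fda_approved"]:
        raise FormatError(
            "profile metadata must have columns ['profile_id', 'quality', 'fda_approved']"
        )
    if meta["profile_id"].duplicated().any():
        raise FormatError("duplicate profile_id in metadata")
    meta = meta.set_index("profile_id")

    gene_space = sorted(df["gene"].unique())
    n = len(gene_space)
    profiles: dict[str, DrugProfile] = {}
    for pid, sub in df.groupby("profile_id", sort=True):
        if sub["gene"].duplicated().any():
            raise FormatError(f"profile {pid!r} scores a gene more than once")
        if len(sub) != n:
            raise FormatError(
                f"profile {pid!r} scores {len(sub)} genes; gene space has {n}"
            )
        drugs = sub["drug_id"].unique()
        if len(drugs) != 1:
            raise FormatError(f"profile {pid!r} maps to multiple drugs: {list(drugs)}")
        if pid not in meta.index:
            raise FormatError(f"profile {pid!r} missing from metadata")
        scores = pd.Series(sub["score"].to_numpy(), index=sub["gene"].to_numpy())
        scores = scores.reindex(gene_space)
        profiles[str(pid)] = DrugProfile(
            drug_id=str(drugs[0]),
            scores=scores,
            quality=bool(meta.at[pid, "quality"]),
            fda_approved=bool(meta.at[pid, "fda_approved"]),
        )
    return DrugProfileLibrary(profiles, gene_space)


def write_drug_profiles(
    lib: DrugProfileLibrary, path: str | Path, meta_path: str | Path
) -> None:
    recs = []
    meta = []
    for pid, prof in lib.profiles.items():
        for g, sc in prof.scores.items():
            recs.append((pid, prof.drug_id, g, sc))
        meta.append((pid, prof.quality, prof.fda_approved))
    pd.DataFrame(recs, columns=["profile_id", "drug_id", "gene", "score"]).to_csv(
        path, sep="\t", index=False
    )
    pd.DataFrame(meta, columns=["profile_id", "quality", "fda_approved"]).to_csv(
        meta_path, sep="\t", index=False
    )


def read_drug_targets(
    path: str | Path, source_vocabulary: tuple[str, ...] = TARGET_SOURCE_DBS
) -> DrugTargetTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["drug_id", "target_id", "source_db"]:
        raise FormatError(
            "drug-target table must have columns ['drug_id', 'target_id', 'source_db']"
        )
    return DrugTargetTable(df, source_vocabulary)


def write_drug_targets(tab: DrugTargetTable, path: str | Path) -> None:
    tab.rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# orthologs


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column source->destination map, keeping only 1:1 pairs.

    Rows whose source or destination occurs more than once are dropped with
    a summary log line; no collapse heuristic is applied.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["src", "dst"])
    if len(df) and df.iloc[0, 0].lower() in {"source", "source_gene", "human_gene"}:
        df = df.iloc[1:]
    df = df.dropna().drop_duplicates()
    src_ok = ~df["src"].duplicated(keep=False)
    dst_ok = ~df["dst"].duplicated(keep=False)
    kept = df[src_ok & dst_ok]
    dropped = len(df) - len(kept)
    if dropped:
        logger.info("ortholog map: dropped %d many-to-many rows of %d", dropped, len(df))
    return OrthologMap(dict(zip(kept["src"], kept["dst"])), n_dropped_ambiguous=dropped)


def apply_ortholog_map(genes: Sequence[str], omap: OrthologMap) -> list[str]:
    """Translate genes through the map; unmapped genes are dropped (logged)."""
    out = [omap.mapping[g] for g in genes if g in omap.mapping]
    n_drop = len(genes) - len(out)
    if n_drop:
        logger.info("ortholog mapping dropped %d of %d genes", n_drop, len(genes))
    return out


# ---------------------------------------------------------------------------
# networks


def write_network(net, path: str | Path, json_path: str | Path | None = None) -> None:
    """Write a pathway network as GraphML plus a JSON edge-list twin.

    Node attributes (enrichment factor, p, FDR, cluster, flip class) and
    edge attributes (overlap size, Jaccard, p) travel with the graph; XML
    escaping is handled by the GraphML writer.
    """
    graph = net if isinstance(net, nx.Graph) else net.graph
    path = Path(path)
    nx.write_graphml(graph, path)
    if json_path is None:
        json_path = path.with_suffix(".json")
    payload = {
        "nodes": [{"id": n, **graph.nodes[n]} for n in graph.nodes],
        "edges": [
            {"source": u, "target": v, **graph.edges[u, v]} for u, v in graph.edges
        ],
    }
    Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
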