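"""Assignment of miRNAs to genomic clusters by distance chaining.

A miRNA cluster is a set of miRNA genes co-located within a short genomic
span: loci are chained per chromosome whenever the gap between consecutive
intervals is at most ``max_gap`` base pairs (default 10 kb). Named family
clusters (e.g. miR-17/92, whose paralog loci sit on chromosome 13 and the
X chromosome) take precedence over genomic chaining for their members.
Singletons — miRNAs with no neighbour within the gap — are reported as
unclustered and excluded from cluster-level statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_types import MirnaAnnotation, ValidationError

DEFAULT_MAX_GAP_BP = 10_000


class AmbiguityError(ValueError):
    """A genomic cluster overlaps more than one labelled locus."""


@dataclass(frozen=True)
class LocusLabel:
    """A named genomic span (e.g. the 14q32 cytoband → ``c14mc``)."""

    chromosome: str
    start: int
    end: int
    name: str


@dataclass
class ClusterMap:
    """Ordered cluster → member assignment plus the leftover singletons."""

    clusters: list[tuple[str, list[str]]]
    unclustered: list[str]
    annotations: dict[str, MirnaAnnotation] = field(default_factory=dict)

    @property
    def membership(self) -> dict[str, str]:
        return {m: name for name, members in self.clusters for m in members}

    def cluster_names(self) -> list[str]:
        return [name for name, _ in self.clusters]

    def members(self, cluster_name: str) -> list[str]:
        for name, members in self.clusters:
            if name == cluster_name:
                return list(members)
        raise KeyError(f"unknown cluster {cluster_name!r}")

    def ordered_mirnas(self, clusters: Sequence[str] | None = None) -> list[str]:
        """All member miRNAs, cluster by cluster, in genomic order."""
        names = list(clusters) if clusters is not None else self.cluster_names()
        return [m for name in names for m in self.members(name)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, members in self.clusters:
            for m in members:
                a = self.annotations.get(m)
                rows.append(
                    {
                        "mirna_id": m,
                        "cluster": name,
                        "chromosome": a.chromosome if a else "",
                        "start": a.start if a else "",
                        "end": a.end if a else "",
                    }
                )
        for m in self.unclustered:
            a = self.annotations.get(m)
            rows.append(
                {
                    "mirna_id": m,
                    "cluster": "unclustered",
                    "chromosome": a.chromosome if a else "",
                    "start": a.start if a else "",
                    "end": a.end if a else "",
                }
            )
        return pd.DataFrame(rows)


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (0, f"{int(c):09d}") if c.isdigit() else (1, c)


def assign_clusters(
    annotations: Iterable[MirnaAnnotation],
    max_gap: int = DEFAULT_MAX_GAP_BP,
) -> ClusterMap:
    """Chain miRNA loci into clusters by single-linkage within ``max_gap``.

    Per chromosome, annotations are sorted by start; a new chain starts
    whenever the gap from the previous interval's end to the next start
    exceeds ``max_gap`` (overlaps count as gap 0). Chains of one go to
    ``unclustered``. miRNAs sharing a ``family`` label are pulled out first
    and merged into one named cluster regardless of chromosome, ordered by
    (chromosome, start).
    """
    annotations = list(annotations)
    if not annotations:
        raise ValidationError("no annotations supplied")
    ids = [a.mirna_id for a in annotations]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate annotations for {dups}")
    ann_by_id = {a.mirna_id: a for a in annotations}

    family_members: dict[str, list[MirnaAnnotation]] = {}
    genomic: list[MirnaAnnotation] = []
    for a in annotations:
        if a.family:
            family_members.setdefault(a.family, []).append(a)
        else:
            genomic.append(a)

    clusters: list[tuple[str, list[str]]] = []
    unclustered: list[str] = []

    by_chrom: dict[str, list[MirnaAnnotation]] = {}
    for a in genomic:
        by_chrom.setdefault(a.chromosome, []).append(a)
    counter: dict[str, int] = {}
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        members = sorted(by_chrom[chrom], key=lambda a: (a.start, a.end, a.mirna_id))
        chain: list[MirnaAnnotation] = []
        chain_end = None
        for a in members + [None]:  # sentinel flushes the last chain
            if a is not None and (chain_end is None or a.start - chain_end <= max_gap):
                chain.append(a)
                chain_end = max(chain_end or a.end, a.end)
                continue
            if len(chain) >= 2:
                counter[chrom] = counter.get(chrom, 0) + 1
                name = f"{chrom}_cluster{counter[chrom]}"
                clusters.append((name, [c.mirna_id for c in chain]))
            elif chain:
                unclustered.append(chain[0].mirna_id)
            if a is not None:
                chain = [a]
                chain_end = a.end
    for fam in sorted(family_members):
        members = sorted(
            family_members[fam],
            key=lambda a: (_chrom_sort_key(a.chromosome), a.start, a.mirna_id),
        )
        clusters.append((fam, [a.mirna_id for a in members]))
    return ClusterMap(clusters=clusters, unclustered=unclustered, annotations=ann_by_id)


def name_clusters(
    cluster_map: ClusterMap,
    locus_labels: Sequence[LocusLabel] | Mapping[str, tuple[str, int, int]],
) -> ClusterMap:
    """Rename genomic clusters that overlap a labelled locus.

    ``locus_labels`` may be a sequence of :class:`LocusLabel` or a mapping
    ``name -> (chromosome, start, end)``. A cluster whose genomic span
    overlaps exactly one label takes its name; overlapping two labels is an
    error. Family clusters and unlabelled clusters keep their names.
    """
    if isinstance(locus_labels, Mapping):
        labels = [
            LocusLabel(chrom, start, end, name)
            for name, (chrom, start, end) in locus_labels.items()
        ]
    else:
        labels = list(locus_labels)
    renamed: list[tuple[str, list[str]]] = []
    for name, members in cluster_map.clusters:
        anns = [cluster_map.annotations[m] for m in members if m in cluster_map.annotations]
        matches = []
        if anns:
            chroms = {a.chromosome for a in anns}
            if len(chroms) == 1:  # family clusters can span chromosomes; skip them
                (chrom,) = chroms
                lo = min(a.start for a in anns)
                hi = max(a.end for a in anns)
                matches = [
                    lab
                    for lab in labels
                    if lab.chromosome == chrom and lab.start <= hi and lo <= lab.end
                ]
        if len(matches) > 1:
            raise AmbiguityError(
                f"cluster {name!r} overlaps labels "
                f"{[lab.name for lab in matches]}"
            )
        renamed.append((matches[0].name if matches else name, members))
    return ClusterMap(
        clusters=renamed,
        unclustered=list(cluster_map.unclustered),
        annotations=dict(cluster_map.annotations),
    )


def write_cluster_map(cluster_map: ClusterMap, path: str | Path) -> None:
    cluster_map.to_frame().to_csv(path, sep="\t", index=False)


def read_cluster_map(path: str | Path) -> ClusterMap:
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "cluster": str})
    clusters: dict[str, list[str]] = {}
    unclustered: list[str] = []
    annotations: dict[str, MirnaAnnotation] = {}
    for _, row in df.iterrows():
        mirna = row["mirna_id"]
        if pd.notna(row.get("chromosome")) and str(row.get("chromosome")):
            try:
                annotations[mirna] = MirnaAnnotation(
                    mirna_id=mirna,
                    chromosome=str(row["chromosome"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            except (ValueError, TypeError):
                pass
        if row["cluster"] == "unclustered":
            unclustered.append(mirna)
        else:
            clusters.setdefault(row["cluster"], []).append(mirna)
    return ClusterMap(
        clusters=list(clusters.items()),
        unclustered=unclustered,
        annotations=annotations,
    )


def cluster_summary_json(cluster_map: ClusterMap, path: str | Path) -> None:
    summary = {}
    for name, members in cluster_map.clusters:
        anns = [cluster_map.annotations[m] for m in members if m in cluster_map.annotations]
        entry: dict = {"size": len(members)}
        if anns:
            entry["span"] = {
                "chromosomes": sorted({a.chromosome for a in anns}),
                "start": min(a.start for a in anns),
                "end": max(a.end for a in anns),
            }
        summary[name] = entry
    summary["unclustered"] = {"size": len(cluster_map.unclustered)}
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
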