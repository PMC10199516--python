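"""Readers and writers for the tabular interchange formats.

All tables are UTF-8 TSVs with a header row and '.' decimals. The ANI
reader additionally accepts headerless fastANI output (query, reference,
ANI, fragments_mapped, fragments_total), computing the overlap fraction as
fragments_mapped / fragments_total. A tolerant GenBank-subset reader pulls
domain labels out of antiSMASH-style feature qualifiers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import AniTable, GenomeCluster
from .gcf import GeneClusterFamily
from .novelty import NoveltyResult
from .records import BgcRecord, MagRecord
from .specificity import OriginAttribution, SpecificityLabel

_NA = ""


def write_mags(mags: Sequence[MagRecord], path) -> None:
    pd.DataFrame(
        {
            "mag_id": [m.mag_id for m in mags],
            "habitat": [m.habitat for m in mags],
            "group": [m.group or _NA for m in mags],
            "completeness": [m.completeness for m in mags],
            "contamination": [m.contamination for m in mags],
            "taxonomy": [";".join(m.taxonomy) if m.taxonomy else _NA for m in mags],
            "source": [m.source for m in mags],
        }
    ).to_csv(path, sep="\t", index=False)


def read_mags(path) -> list[MagRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            MagRecord(
                mag_id=row.mag_id,
                habitat=row.habitat,
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                group=getattr(row, "group", _NA) or None,
                taxonomy=tuple(row.taxonomy.split(";")) if getattr(row, "taxonomy", "") else None,
                source=getattr(row, "source", "this-study") or "this-study",
            )
        )
    return out


def write_ani(table: AniTable, path) -> None:
    rows = []
    for (q, r), (ani, overlap) in sorted(table.directed_items()):
        rev = table._directed.get((r, q))
        rows.append((q, r, ani, overlap, rev[1] if rev else overlap))
    pd.DataFrame(rows, columns=["query_id", "ref_id", "ani", "overlap_q", "overlap_r"]).to_csv(
        path, sep="\t", index=False
    )


def read_ani(path) -> AniTable:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    table = AniTable()
    if first.startswith("query_id\t"):
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples(index=False):
            table.add(row.query_id, row.ref_id, float(row.ani), float(row.overlap_q))
            table.add(row.ref_id, row.query_id, float(row.ani), float(row.overlap_r))
    else:
        # headerless fastANI layout
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["query", "reference", "ani", "fragments_mapped", "fragments_total"],
        )
        for row in df.itertuples(index=False):
            if row.query == row.reference:
                continue
            table.add(
                str(row.query),
                str(row.reference),
                float(row.ani),
                float(row.fragments_mapped) / float(row.fragments_total),
            )
    return table


def write_bgcs(bgcs: Sequence[BgcRecord], path) -> None:
    pd.DataFrame(
        {
            "bgc_id": [b.bgc_id for b in bgcs],
            "mag_id": [b.mag_id for b in bgcs],
            "class": [b.bgc_class for b in bgcs],
            "domains": [";".join(b.domains) for b in bgcs],
            "is_reference": [int(b.is_reference) for b in bgcs],
            "ecosystem": [b.ecosystem or _NA for b in bgcs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_bgcs(path, is_reference: bool | None = None, ecosystem: str | None = None) -> list[BgcRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.to_dict("records"):
        ref = row.get("is_reference", "")
        out.append(
            BgcRecord(
                bgc_id=row["bgc_id"],
                mag_id=row["mag_id"],
                bgc_class=row["class"],
                domains=tuple(row["domains"].split(";")) if row["domains"] else (),
                is_reference=bool(int(ref)) if ref != "" else bool(is_reference),
                ecosystem=(row.get("ecosystem", "") or ecosystem) or None,
            )
        )
    return out


def write_clusters(clusters: Sequence[GenomeCluster], mags: Sequence[MagRecord], path) -> None:
    habitat = {m.mag_id: m.habitat for m in mags}
    rows = []
    for c in clusters:
        for m in c.member_mag_ids:
            rows.append(
                (c.cluster_id, c.level, c.representative_mag_id, m,
                 habitat.get(m, _NA), int(c.is_habitat_specific))
            )
    pd.DataFrame(
        rows,
        columns=["cluster_id", "level", "representative", "mag_id", "habitat", "is_habitat_specific"],
    ).to_csv(path, sep="\t", index=False)


def read_clusters(path) -> list[GenomeCluster]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        out.append(
            GenomeCluster(
                cluster_id=cid,
                level=grp["level"].iloc[0],
                representative_mag_id=grp["representative"].iloc[0],
                member_mag_ids=tuple(grp["mag_id"]),
                habitat_set=frozenset(h for h in grp["habitat"] if h),
            )
        )
    return out


def write_edges(edges: Sequence[tuple[str, str, float]], path) -> None:
    pd.DataFrame(edges, columns=["src", "dst", "distance"]).to_csv(path, sep="\t", index=False)


def write_families(families: Sequence[GeneClusterFamily], path) -> None:
    rows = [
        (f.gcf_id, m, int(f.is_known)) for f in families for m in f.member_bgc_ids
    ]
    pd.DataFrame(rows, columns=["gcf_id", "bgc_id", "is_known"]).to_csv(path, sep="\t", index=False)


def write_specificity(labels: Sequence[SpecificityLabel], path) -> None:
    pd.DataFrame(
        {
            "subject_id": [l.subject_id for l in labels],
            "scope": [l.scope for l in labels],
            "is_habitat_specific": [int(l.is_habitat_specific) for l in labels],
            "habitat": [l.habitat or _NA for l in labels],
        }
    ).to_csv(path, sep="\t", index=False)


def write_attributions(attributions: Sequence[OriginAttribution], path) -> None:
    pd.DataFrame(
        {
            "bgc_id": [a.bgc_id for a in attributions],
            "origin_class": [a.origin_class for a in attributions],
            "species_id": [a.species_cluster_id for a in attributions],
            "genotype_id": [a.genotype_cluster_id for a in attributions],
        }
    ).to_csv(path, sep="\t", index=False)


def write_novelty(results: Sequence[NoveltyResult], path) -> None:
    rows = []
    for r in results:
        for eco in sorted(r.distances):
            rows.append(
                (r.bgc_id, eco, r.distances[eco], r.nearest[eco],
                 r.novelty_class[eco], r.uniqueness_class or _NA)
            )
    pd.DataFrame(
        rows,
        columns=["bgc_id", "ecosystem", "distance", "nearest_centroid", "novelty_class", "uniqueness_class"],
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True), encoding="utf-8")


def read_bgc_genbank(path, mag_id: str = "", bgc_class: str = "other") -> BgcRecord:
    """Read one BGC from an antiSMASH-style GenBank subset file.

    Domain labels are taken, in feature order, from ``aSDomain``/``domain``
    qualifiers of the record's features; a ``product`` qualifier on a
    region/protocluster feature provides the class. Records without such
    qualifiers yield an empty domain list.
    """
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "genbank"))
    domains: list[str] = []
    cls = bgc_class
    for feat in record.features:
        if feat.type in ("region", "protocluster", "cand_cluster"):
            products = feat.qualifiers.get("product")
            if products:
                cls = products[0]
        for key in ("aSDomain", "domain", "domains"):
            domains.extend(feat.qualifiers.get(key, []))
    return BgcRecord(
        bgc_id=record.id or Path(path).stem,
        mag_id=mag_id or (record.annotations.get("source") or "unknown"),
        bgc_class=cls,
        domains=tuple(domains),
    )
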