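"""Assembly of stacked per-residue feature tables and summary metrics.

The feature table has one row per residue and one column per track, with
region lists flattened to 0/1 indicator columns; the column order is the
insertion order of the bundle plus sorted region labels, so identical inputs
and configuration always produce byte-identical output. Summaries report
class contents as whole percents, charge-decoration scalars at 3 decimals,
and counts; stages that were not run are absent from the summary rather than
reported as zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import charge, complexity, composition, motifs
from .composition import ResidueClassDefinitions, round_half_away
from .seqio import FeatureTrack, Region, SequenceRecord

#: Classes whose percentages appear in the summary, in report order.
SUMMARY_CLASSES = ("aromatic", "hydrophobic", "polar", "charged")


@dataclass
class FeatureBundle:
    """Tracks, regions and summary scalars for one sequence."""

    sequence: SequenceRecord
    tracks: dict = field(default_factory=dict)   # name -> FeatureTrack
    regions: dict = field(default_factory=dict)  # label -> list of regions
    scalars: dict = field(default_factory=dict)  # metric name -> value

    def add_track(self, track: FeatureTrack) -> None:
        if len(track) != self.sequence.length:
            raise ValueError(
                f"track {track.name!r} length {len(track)} != sequence length "
                f"{self.sequence.length}"
            )
        self.tracks[track.name] = track

    def add_regions(self, label: str, region_list: Iterable) -> None:
        region_list = list(region_list)
        for r in region_list:
            if r.end > self.sequence.length:
                raise ValueError(
                    f"region [{r.start}, {r.end}] outside sequence of length "
                    f"{self.sequence.length}"
                )
        self.regions[label] = region_list


def build_feature_table(b: FeatureBundle) -> pd.DataFrame:
    """One row per residue; tracks as columns, regions as 0/1 indicators."""
    n = b.sequence.length
    data = {
        "position": np.arange(1, n + 1),
        "residue": list(b.sequence.residues),
    }
    for name, track in b.tracks.items():
        data[name] = list(track.values)
    for label in sorted(b.regions):
        indicator = np.zeros(n, dtype=int)
        for r in b.regions[label]:
            indicator[r.start - 1 : r.end] = 1
        data[f"in_{label}"] = indicator
    return pd.DataFrame(data)


def summarize(b: FeatureBundle, defs: Optional[ResidueClassDefinitions] = None) -> dict:
    """Whole-sequence summary: class percents, decoration scalars, counts."""
    defs = defs or ResidueClassDefinitions()
    s = b.sequence
    summary: dict = {"id": s.id, "length": s.length}
    for name in SUMMARY_CLASSES:
        summary[f"{name}_percent"] = composition.class_percent(s, name, defs)
    for key, value in b.scalars.items():
        summary[key] = round(value, 3) if isinstance(value, float) else value
    for label, region_list in b.regions.items():
        summary[f"n_{label}"] = len(region_list)
        covered = np.zeros(s.length, dtype=bool)
        for r in region_list:
            covered[r.start - 1 : r.end] = True
        summary[f"{label}_coverage_percent"] = round_half_away(
            100.0 * covered.sum() / s.length
        )
    return summary


def analyze_sequence(
    s: SequenceRecord,
    defs: Optional[ResidueClassDefinitions] = None,
    window: int = complexity.DEFAULT_WINDOW,
    entropy_threshold: float = complexity.DEFAULT_ENTROPY_THRESHOLD,
    catalog: Optional[list] = None,
    charge_window: int = 10,
) -> FeatureBundle:
    """Default single-sequence pipeline: composition tracks, entropy profile,
    LCR calls, charge tracks and scalars, motif and GAR scanning."""
    defs = defs or ResidueClassDefinitions()
    bundle = FeatureBundle(sequence=s)

    for name in ("polar", "hydrophobic", "aromatic", "pi_system",
                 "positive", "negative", "hbond_donor", "hbond_acceptor",
                 "hbond_both"):
        bundle.add_track(composition.class_track(s, name, defs))

    profile = complexity.shannon_residue(s, window)
    bundle.add_track(FeatureTrack(
        name=f"entropy_w{window}", values=profile.values.tolist(), kind="real"
    ))
    bundle.add_regions("lcr", complexity.detect_lcr_entropy(s, window, entropy_threshold))

    v = charge.charge_vector(s, "decoration")
    bundle.add_track(charge.ncpr_track(v, charge_window))
    bundle.add_track(charge.fcr_track(v, charge_window))
    deco = charge.charge_decoration(s)
    bundle.scalars.update(
        f_plus=deco.f_plus, f_minus=deco.f_minus, fcr=deco.fcr,
        ncpr=deco.ncpr, ocs=deco.ocs, scd=deco.scd,
        cider_class=deco.cider_class,
    )

    catalog = catalog if catalog is not None else motifs.load_catalog()
    hits = motifs.scan_catalog(s, catalog)
    bundle.add_regions("motif", [
        Region(start=h.start, end=h.end, label=h.name) for h in hits
    ])
    bundle.add_regions("gar", motifs.detect_gar(s))
    bundle.add_regions("repeat", motifs.detect_tandem_repeats(s))
    return bundle


def regions_to_bed(regions: Iterable, sequence_id: str) -> str:
    """BED-like TSV: 0-based half-open intervals (converted from the 1-based
    inclusive internal convention; the header documents the conversion)."""
    lines = [
        "# BED-like export: 0-based half-open coordinates "
        "(internal convention is 1-based inclusive: start0 = start - 1, end0 = end)",
        "# columns: sequence\tstart\tend\tlabel",
    ]
    for r in regions:
        lines.append(f"{sequence_id}\t{r.start - 1}\t{r.end}\t{r.label or '.'}")
    return "\n".join(lines) + "\n"


def write_outputs(bundle: FeatureBundle, out_prefix: str) -> dict:
    """Write <prefix>.features.tsv, <prefix>.summary.json, <prefix>.regions.bed;
    returns the paths written."""
    table = build_feature_table(bundle)
    features_path = f"{out_prefix}.features.tsv"
    table.to_csv(features_path, sep="\t", index=False, float_format="%.6f")

    summary_path = f"{out_prefix}.summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summarize(bundle), fh, indent=2, sort_keys=True)
        fh.write("\n")

    all_regions = [r for label in sorted(bundle.regions)
                   for r in bundle.regions[label]]
    bed_path = f"{out_prefix}.regions.bed"
    with open(bed_path, "w") as fh:
        fh.write(regions_to_bed(all_regions, bundle.sequence.id))
    return {"features": features_path, "summary": summary_path, "regions": bed_path}
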