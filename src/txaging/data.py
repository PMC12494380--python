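"""The cohort bundle: expression, splicing, metadata, annotation, truth.

All downstream stages consume a :class:`Cohort`: a sample table plus
column-aligned TPM (genes x samples), PSI (events x samples, values in
[0, 1] with NaN for undetected events) and junction-count matrices, and a
feature-annotation table mapping every gene and splice event to a
chromosome and every event to its host gene.

The on-disk form is a directory of tab-delimited files (``tpm.tsv``,
``psi.tsv``, ``junction_counts.tsv``, ``samples.tsv``, ``features.tsv``)
plus ``truth.json`` recording any planted effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_TYPES = ("SE", "A5SS", "A3SS", "RI")

SAMPLE_COLUMNS = ["donor", "sex", "age", "tissue", "region"]
FEATURE_COLUMNS = ["kind", "gene", "chromosome", "event_type", "start", "end"]


@dataclass
class Cohort:
    """Paired expression/splicing matrices with sample metadata.

    Attributes
    ----------
    samples
        One row per sample, indexed by sample id, with columns
        ``donor``, ``sex`` ("F"/"M"), ``age`` (years), ``tissue`` and
        optional ``region``.
    tpm
        Genes x samples, non-negative.
    psi
        Events x samples in [0, 1]; NaN marks a missing quantification.
    junction_counts
        Events x samples, non-negative read support for each event.
    features
        Per gene/event annotation: ``kind`` ("gene"/"event"), host
        ``gene``, ``chromosome``, ``event_type`` (SE/A5SS/A3SS/RI for
        events), 0-based half-open splice-site interval ``start``/``end``.
    truth
        Planted-effect records (empty for real data).
    """

    samples: pd.DataFrame
    tpm: pd.DataFrame
    psi: pd.DataFrame
    junction_counts: pd.DataFrame
    features: pd.DataFrame
    truth: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = list(self.samples.index)
        for name in ("tpm", "psi", "junction_counts"):
            mat = getattr(self, name)
            if list(mat.columns) != ids:
                raise ValueError(f"{name} columns are not aligned with the sample table")
        psi_vals = self.psi.to_numpy(float)
        observed = psi_vals[~np.isnan(psi_vals)]
        if observed.size and (observed.min() < 0 or observed.max() > 1):
            raise ValueError("PSI values must lie in [0, 1]")
        events = self.features.index[self.features["kind"] == "event"]
        hosts = self.features.loc[events, "gene"]
        if hosts.isna().any():
            raise ValueError("every splice event must map to a host gene")

    @property
    def genes(self) -> pd.Index:
        return self.features.index[self.features["kind"] == "gene"]

    @property
    def events(self) -> pd.Index:
        return self.features.index[self.features["kind"] == "event"]

    def event_gene_map(self) -> pd.Series:
        """Host gene of each splice event."""
        return self.features.loc[self.events, "gene"]

    def sex_chromosome_features(self) -> pd.Index:
        """Ids of genes/events encoded on chrX or chrY."""
        mask = self.features["chromosome"].isin(["chrX", "chrY", "X", "Y"])
        return self.features.index[mask]

    def subset_samples(self, sample_ids) -> "Cohort":
        ids = list(sample_ids)
        return Cohort(
            samples=self.samples.loc[ids],
            tpm=self.tpm[ids],
            psi=self.psi[ids],
            junction_counts=self.junction_counts[ids],
            features=self.features,
            truth=self.truth,
        )

    def write(self, outdir) -> None:
        """Write the tab-delimited bundle (and ``truth.json``) to a directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.tpm.to_csv(out / "tpm.tsv", sep="\t")
        self.psi.to_csv(out / "psi.tsv", sep="\t")
        self.junction_counts.to_csv(out / "junction_counts.tsv", sep="\t")
        self.samples.to_csv(out / "samples.tsv", sep="\t")
        self.features.to_csv(out / "features.tsv", sep="\t")
        truth = [t if isinstance(t, dict) else asdict(t) for t in self.truth]
        for rec in truth:
            if isinstance(rec.get("target_features"), (set, frozenset)):
                rec["target_features"] = sorted(rec["target_features"])
        (out / "truth.json").write_text(json.dumps(truth, indent=1, default=str))

    @classmethod
    def read(cls, indir) -> "Cohort":
        """Load a bundle previously written by :meth:`write`."""
        ind = Path(indir)
        samples = pd.read_csv(ind / "samples.tsv", sep="\t", index_col=0)
        tpm = pd.read_csv(ind / "tpm.tsv", sep="\t", index_col=0)
        psi = pd.read_csv(ind / "psi.tsv", sep="\t", index_col=0)
        jc = pd.read_csv(ind / "junction_counts.tsv", sep="\t", index_col=0)
        features = pd.read_csv(ind / "features.tsv", sep="\t", index_col=0)
        truth_path = ind / "truth.json"
        truth = json.loads(truth_path.read_text()) if truth_path.exists() else []
        return cls(samples, tpm, psi, jc, features, truth)
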