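"""Seeded generator of messy literature-style bioactivity corpora.

The generator emulates how published SAR data actually goes wrong: each
compound-target pair has a true potency on the -log10 molar scale, every
independent measurement adds inter-assay noise, values are rendered in a
random unit dialect or as a logarithmic type, later papers re-cite the
original measurement (possibly rounded to 2-3 significant figures), and
some citations slip the units by exactly 3 or 6 decades. Every injected
defect is recorded in a ground-truth table keyed by record id, so the
precision and recall of each flagging operation can be measured without
any external data.

What it does *not* emulate: structure-level errors (stereochemistry,
salts), systematic inter-lab bias, correlated assay series, or free-text
noise in assay descriptions. Passing tests on this corpus demonstrate
that the detectors implement their rules exactly, not that the rules
catch every real-world defect.
"""

from __future__ import annotations

import math
from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, model_validator

from .config import CurationConfig, default_config
from .flags import value_out_of_range
from .records import (
    MISSING_DATA,
    OUT_OF_RANGE,
    TRANSCRIPTION_ERROR,
    ActivityRecord,
    AssayRecord,
    CompoundRecord,
)
from .standardize import round_sig, round_standard_value

#: Published-unit dialects used for rendering, as (normalized factor to
#: nM, spellings). Molar dialects only: citations must land in the same
#: (type, unit) group as their original for like-for-like comparison.
_NM_SPELLINGS = ["nM", "nmol/L", "nmol.l-1"]
_DIALECTS = [
    (1.0e3, ["uM", "umol/L", "µM", "micromolar"]),
    (1.0e6, ["mM", "mmol/L"]),
    (1.0e9, ["M", "mol/L"]),
    (1.0e-3, ["pM", "pmol/L"]),
]
_LOG_NAME = {"IC50": "pIC50", "Ki": "pKi", "EC50": "pEC50", "Kd": "pKd"}
_STANDARD_TYPES = ["IC50", "Ki", "EC50", "Kd"]


class GeneratorParams(BaseModel):
    """Study conditions for one synthetic corpus.

    Potencies are dimensionless -log10 molar; all probabilities are per
    applicable record. The defaults give roughly 6,300 records.
    """

    n_compounds: int = 300
    n_targets: int = 6
    n_documents: int = 50
    measurements_per_pair: Union[int, tuple[int, int]] = (2, 5)
    true_pactivity_mean: float = 6.5
    true_pactivity_sd: float = 1.5
    assay_noise_sd: float = 0.5
    p_log_reported: float = 0.2
    p_unit_dialect: float = 0.5
    p_citation: float = 0.05
    p_citation_rounded: float = 0.5
    p_transcription_error: float = 0.02
    p_missing: float = 0.01
    transcription_decades: tuple[int, ...] = (3, 6)
    fragment_fraction: float = 0.1
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        for name in (
            "p_log_reported",
            "p_unit_dialect",
            "p_citation",
            "p_citation_rounded",
            "p_transcription_error",
            "p_missing",
            "fragment_fraction",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.p_citation + self.p_transcription_error > 1.0:
            raise ValueError("p_citation + p_transcription_error must be <= 1")
        if self.true_pactivity_sd < 0 or self.assay_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not set(self.transcription_decades) <= {3, 6}:
            raise ValueError("transcription_decades must be a subset of {3, 6}")
        if min(self.n_compounds, self.n_targets, self.n_documents) < 1:
            raise ValueError("corpus dimensions must be positive")
        return self


class SyntheticGroundTruth(BaseModel):
    """Per-record defect labels plus injection tallies.

    Labels: 'clean', 'missing', 'out_of_range_injected',
    'citation_duplicate_of:<record_id>', 'transcription_error_of:<record_id>'.
    ``intended_standard`` holds the (standard type, standard value in nM)
    the published fields were rendered from.
    """

    labels: dict[str, list[str]]
    intended_standard: dict[str, tuple[str, float]] = {}
    n_citation_eligible: int = 0
    n_citations_injected: int = 0
    n_transcriptions_injected: int = 0
    n_missing_injected: int = 0


def _measurement_count(spec, rng: np.random.Generator, cap: int) -> int:
    if isinstance(spec, int):
        m = spec
    else:
        low, high = spec
        m = int(rng.integers(low, high + 1))
    return max(1, min(m, cap))


def _render(
    v_std: float,
    stype: str,
    rng: np.random.Generator,
    params: GeneratorParams,
) -> tuple[str, float, Optional[str]]:
    """Render an intended standard value (nM) as published fields."""
    if stype in _LOG_NAME and rng.random() < params.p_log_reported:
        return _LOG_NAME[stype], 9.0 - math.log10(v_std), None
    if rng.random() < params.p_unit_dialect:
        factor, spellings = _DIALECTS[int(rng.integers(len(_DIALECTS)))]
        return stype, v_std / factor, spellings[int(rng.integers(len(spellings)))]
    return stype, v_std, _NM_SPELLINGS[int(rng.integers(len(_NM_SPELLINGS)))]


def generate_corpus(
    params: GeneratorParams, config: Optional[CurationConfig] = None
) -> tuple[
    list[ActivityRecord],
    list[CompoundRecord],
    list[AssayRecord],
    SyntheticGroundTruth,
]:
    """Generate a messy corpus with ground truth, reproducibly for a seed.

    A single RNG stream is consumed in a fixed order (compounds, then
    compound x target pairs in index order, documents sorted within each
    pair), so a given seed always yields byte-identical output.
    """
    config = config if config is not None else default_config()
    rng = np.random.default_rng(params.seed)

    compounds = []
    mw_of: dict[str, float] = {}
    for i in range(params.n_compounds):
        cid = f"C{i:05d}"
        if rng.random() < params.fragment_fraction:
            mw = float(np.round(rng.uniform(160.0, 349.0), 1))
        else:
            mw = float(np.round(rng.uniform(350.0, 650.0), 1))
        compounds.append(CompoundRecord(compound_id=cid, molecular_weight=mw))
        mw_of[cid] = mw

    doc_ids = [f"D{i:04d}" for i in range(params.n_documents)]
    year_of = {d: 1980 + i for i, d in enumerate(doc_ids)}
    target_ids = [f"T{i:03d}" for i in range(params.n_targets)]

    assays: dict[tuple[str, str], AssayRecord] = {}

    def assay_for(doc: str, target: str) -> str:
        key = (doc, target)
        if key not in assays:
            assays[key] = AssayRecord(
                assay_id=f"A{len(assays):05d}",
                document_id=doc,
                description=(
                    f"Displacement of radioligand from recombinant {target} "
                    f"reported in {doc}"
                ),
                target_id=target,
                relationship_type="D",
            )
        return assays[key].assay_id

    records: list[ActivityRecord] = []
    labels: dict[str, list[str]] = {}
    intended: dict[str, tuple[str, float]] = {}
    truth = SyntheticGroundTruth(labels={})

    def add_record(
        doc: str, compound: str, target: str, stype: str, v_std: Optional[float]
    ) -> str:
        rid = f"R{len(records):06d}"
        if v_std is None:
            rec = ActivityRecord(
                record_id=rid,
                document_id=doc,
                document_year=year_of[doc],
                assay_id=assay_for(doc, target),
                compound_id=compound,
                published_type=stype,
                published_relation=None,
                published_value=None,
                published_units=None,
            )
        else:
            ptype, pval, punits = _render(v_std, stype, rng, params)
            rec = ActivityRecord(
                record_id=rid,
                document_id=doc,
                document_year=year_of[doc],
                assay_id=assay_for(doc, target),
                compound_id=compound,
                published_type=ptype,
                published_relation="=",
                published_value=pval,
                published_units=punits,
            )
            intended[rid] = (stype, v_std)
        records.append(rec)
        labels[rid] = []
        return rid

    for ci in range(params.n_compounds):
        cid = f"C{ci:05d}"
        for target in target_ids:
            p_true = rng.normal(params.true_pactivity_mean, params.true_pactivity_sd)
            stype = _STANDARD_TYPES[int(rng.integers(len(_STANDARD_TYPES)))]
            m = _measurement_count(
                params.measurements_per_pair, rng, params.n_documents
            )
            docs = sorted(
                rng.choice(params.n_documents, size=m, replace=False).tolist()
            )
            original_rid: Optional[str] = None
            original_value: Optional[float] = None
            for k, doc_idx in enumerate(docs):
                doc = doc_ids[doc_idx]
                kind = "independent"
                if k > 0 and original_value is not None:
                    truth.n_citation_eligible += 1
                    u = rng.random()
                    if u < params.p_citation:
                        kind = "citation"
                    elif u < params.p_citation + params.p_transcription_error:
                        kind = "transcription"

                if kind == "independent":
                    if rng.random() < params.p_missing:
                        rid = add_record(doc, cid, target, stype, None)
                        labels[rid].append("missing")
                        truth.n_missing_injected += 1
                        continue
                    p_meas = p_true + rng.normal(0.0, params.assay_noise_sd)
                    v_std = round_standard_value(10.0 ** (9.0 - p_meas))
                    rid = add_record(doc, cid, target, stype, v_std)
                    if k == 0:
                        original_rid, original_value = rid, v_std
                elif kind == "citation":
                    v = original_value
                    if rng.random() < params.p_citation_rounded:
                        v = round_sig(v, int(rng.integers(2, 4)))
                    rid = add_record(doc, cid, target, stype, v)
                    labels[rid].append(f"citation_duplicate_of:{original_rid}")
                    truth.n_citations_injected += 1
                else:  # transcription error: decade slip of a cited value
                    # the later paper reprints the value as published in a
                    # table (2-3 significant figures) with the wrong units
                    v_base = round_sig(original_value, int(rng.integers(2, 4)))
                    decades = params.transcription_decades
                    kdec = decades[int(rng.integers(len(decades)))]
                    sign = 1 if rng.random() < 0.5 else -1
                    v_std = round_standard_value(v_base * 10.0 ** (sign * kdec))
                    rid = add_record(doc, cid, target, stype, v_std)
                    labels[rid].append(f"transcription_error_of:{original_rid}")
                    truth.n_transcriptions_injected += 1

    # Out-of-range labels: any rendered value outside its typical range,
    # excluding transcription records (the pipeline gives those the more
    # specific transcription-error comment).
    for rid, (stype, v_std) in intended.items():
        if any(l.startswith("transcription_error_of:") for l in labels[rid]):
            continue
        rec = records[int(rid[1:])]
        if value_out_of_range(v_std, stype, "nM", mw_of[rec.compound_id], config):
            labels[rid].append("out_of_range_injected")

    for rid in labels:
        if not labels[rid]:
            labels[rid] = ["clean"]

    truth.labels = labels
    truth.intended_standard = intended
    return records, compounds, list(assays.values()), truth


class FlagMetrics(BaseModel):
    tp: int
    fp: int
    fn: int
    precision: Optional[float] = None
    recall: Optional[float] = None


#: flag class -> (record predicate, truth-label predicate)
_FLAG_CLASSES = {
    "missing": (
        lambda r: r.data_validity_comment == MISSING_DATA,
        lambda ls: "missing" in ls,
    ),
    "duplicate": (
        lambda r: r.potential_duplicate,
        lambda ls: any(l.startswith("citation_duplicate_of:") for l in ls),
    ),
    "transcription": (
        lambda r: r.data_validity_comment == TRANSCRIPTION_ERROR,
        lambda ls: any(l.startswith("transcription_error_of:") for l in ls),
    ),
    "out_of_range": (
        lambda r: r.data_validity_comment == OUT_OF_RANGE,
        lambda ls: "out_of_range_injected" in ls,
    ),
}


def evaluate_flags(
    records: list[ActivityRecord], truth: SyntheticGroundTruth
) -> dict[str, FlagMetrics]:
    """Precision and recall of each flag class against the ground truth.

    Precision or recall is ``None`` (undefined) when its denominator is
    zero. Raises ``ValueError`` on a record-id mismatch between the
    curated records and the truth table.
    """
    record_ids = {r.record_id for r in records}
    if record_ids != set(truth.labels):
        raise ValueError("record ids of curated corpus and ground truth differ")
    out: dict[str, FlagMetrics] = {}
    for name, (predicted, actual) in _FLAG_CLASSES.items():
        tp = fp = fn = 0
        for r in records:
            pred = predicted(r)
            act = actual(truth.labels[r.record_id])
            if pred and act:
                tp += 1
            elif pred:
                fp += 1
            elif act:
                fn += 1
        out[name] = FlagMetrics(
            tp=tp,
            fp=fp,
            fn=fn,
            precision=tp / (tp + fp) if tp + fp else None,
            recall=tp / (tp + fn) if tp + fn else None,
        )
    return out
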