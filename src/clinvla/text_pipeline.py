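"""Report structuring and tokenization.

Keeps only the Findings/Diagnosis sections of a free-text report, tokenizes
with a deterministic whitespace+punctuation tokenizer (pluggable behind a
small protocol), and pads or truncates to a fixed 128-token length with
sentence-boundary truncation.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "ReportDocument",
    "TokenSequence",
    "DEFAULT_HEADER_MAP",
    "extract_sections",
    "HashTokenizer",
    "sentence_end_positions",
    "pad_or_truncate",
    "encode_report",
    "remove_stop_phrases",
    "read_reports_jsonl",
    "write_encoded_jsonl",
]

# header -> canonical section; "impression" is a synonym for diagnosis
DEFAULT_HEADER_MAP = {
    "findings": "findings",
    "diagnosis": "diagnosis",
    "impression": "diagnosis",
}

MAX_TEXT_LEN = 128
SENTENCE_END_TOKENS = (".", ";")


@dataclass
class ReportDocument:
    findings: str
    diagnosis: str
    raw: str
    record_id: str = ""
    valid: bool = True


@dataclass
class TokenSequence:
    ids: list[int]
    length: int
    pad_id: int
    truncated: bool

    def __post_init__(self):
        if len(self.ids) != self.length:
            raise ValueError("ids length does not match declared length")


# any alphabetic word followed by a colon starts a section
_ANY_HEADER_RE = re.compile(r"\b([A-Za-z]{2,})\s*:")


def extract_sections(raw: str, header_map: dict[str, str] | None = None,
                     record_id: str = "") -> ReportDocument:
    """Split a report at ``Header:`` markers and keep only the sections whose
    header maps to findings/diagnosis (case-insensitive; first occurrence
    wins).  Sections under unrecognized headers — history, requests, etc. —
    are dropped.

    A report with no recognized section is returned flagged invalid rather
    than raising.
    """
    if not raw:
        raise ValueError("raw report text is empty")
    header_map = header_map or DEFAULT_HEADER_MAP
    sections: dict[str, str] = {}
    matches = list(_ANY_HEADER_RE.finditer(raw))
    for i, m in enumerate(matches):
        canon = header_map.get(m.group(1).lower())
        start = m.end()
        end = matches[i + 1].start() if i + 1 < len(matches) else len(raw)
        if canon in ("findings", "diagnosis") and canon not in sections:
            sections[canon] = raw[start:end].strip()
    findings = sections.get("findings", "")
    diagnosis = sections.get("diagnosis", "")
    return ReportDocument(
        findings=findings,
        diagnosis=diagnosis,
        raw=raw,
        record_id=record_id,
        valid=bool(findings or diagnosis),
    )


def remove_stop_phrases(text: str, phrases) -> str:
    """Optional vague-expression filter; removes each phrase verbatim
    (case-insensitive). Off by default in the pipeline."""
    for p in phrases:
        text = re.sub(re.escape(p), "", text, flags=re.IGNORECASE)
    return re.sub(r"\s+", " ", text).strip()


_TOKEN_RE = re.compile(r"[A-Za-z0-9]+|[^\sA-Za-z0-9]")


class HashTokenizer:
    """Deterministic whitespace+punctuation tokenizer that needs no
    vocabulary file: each lowercased token is hashed into a fixed id range.

    Id 0 is [PAD].  Collisions are possible but rare at default vocab size
    and harmless for the toy encoders used here.
    """

    def __init__(self, vocab_size: int = 4096, pad_id: int = 0):
        if vocab_size < 16:
            raise ValueError("vocab_size too small")
        self.vocab_size = vocab_size
        self.pad_id = pad_id

    def tokenize(self, text: str) -> list[str]:
        return _TOKEN_RE.findall(text.lower())

    def token_to_id(self, token: str) -> int:
        digest = hashlib.blake2b(token.encode(), digest_size=8).digest()
        return int.from_bytes(digest, "big") % (self.vocab_size - 1) + 1

    def encode(self, text: str) -> tuple[list[int], list[str]]:
        toks = self.tokenize(text)
        return [self.token_to_id(t) for t in toks], toks


def sentence_end_positions(tokens: list[str]) -> list[int]:
    """1-based cut positions: position i means 'keep the first i tokens',
    where token i-1 is a sentence terminator."""
    return [i + 1 for i, t in enumerate(tokens) if t in SENTENCE_END_TOKENS]


def pad_or_truncate(ids: list[int], max_len: int = MAX_TEXT_LEN,
                    pad_id: int = 0,
                    sentence_ends: list[int] | None = None) -> TokenSequence:
    """Right-pad short sequences; truncate long ones at the largest sentence
    boundary that fits, falling back to a hard cut at max_len."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(ids) <= max_len:
        out = list(ids) + [pad_id] * (max_len - len(ids))
        return TokenSequence(ids=out, length=max_len, pad_id=pad_id,
                             truncated=False)
    cut = max_len
    if sentence_ends:
        fitting = [e for e in sentence_ends if 0 < e <= max_len]
        if fitting:
            cut = max(fitting)
    out = list(ids[:cut]) + [pad_id] * (max_len - cut)
    return TokenSequence(ids=out, length=max_len, pad_id=pad_id, truncated=True)


def encode_report(raw: str, tokenizer: HashTokenizer | None = None,
                  max_len: int = MAX_TEXT_LEN,
                  header_map: dict[str, str] | None = None,
                  record_id: str = "") -> tuple[ReportDocument, TokenSequence]:
    """Full text path: section extraction -> tokenize -> pad/truncate."""
    tokenizer = tokenizer or HashTokenizer()
    doc = extract_sections(raw, header_map=header_map, record_id=record_id)
    text = (doc.findings + " " + doc.diagnosis).strip()
    ids, toks = tokenizer.encode(text)
    seq = pad_or_truncate(ids, max_len=max_len, pad_id=tokenizer.pad_id,
                          sentence_ends=sentence_end_positions(toks))
    return doc, seq


# --------------------------------------------------------------------------
# JSONL I/O
# --------------------------------------------------------------------------

def read_reports_jsonl(path) -> list[dict]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records


def write_encoded_jsonl(path, docs_and_seqs):
    """Write {record_id, findings, diagnosis, token_ids} per line."""
    with open(path, "w") as fh:
        for doc, seq in docs_and_seqs:
            fh.write(json.dumps({
                "record_id": doc.record_id,
                "findings": doc.findings,
                "diagnosis": doc.diagnosis,
                "token_ids": seq.ids,
            }) + "\n")
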