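"""Independent brute-force oracles used only by the test suite.

Deliberately implemented without the package's rule engine: the case-finding
tables are transcribed here as flat regular-expression scans, kappa as plain
po/pe loops, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import re
import unicodedata


def _norm(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return re.sub(r"\s+", " ", stripped.casefold()).strip()


_MORPH_LISTED = re.compile(
    r"^(M-81403|M-80703|M-82463|M-85603|M-83233|M-85503|M-84303|M-82503"
    r"|M-80033|M-80123|M-80463)$"
)
_M8 = re.compile(r"^M-8")
_MORPH_KW = re.compile(r"non microcit|adenocarcin|squamocell|grandi cell")
_T2 = re.compile(r"^T-2")
_LUNG_KW = re.compile(r"\bpolm|\bbronch")
_NEURO = re.compile(r"^M-82463$")
_UPPER = re.compile(r"^T-2[1-5]")
_RESP_NOS = re.compile(r"^T-20")


def _morpho1(record) -> bool:
    text = _norm(record.diagnosis_text)
    listed = any(_MORPH_LISTED.match(c) for c in record.morphology_codes)
    generic = any(_M8.match(c) for c in record.morphology_codes) and bool(
        _MORPH_KW.search(text)
    )
    return listed or generic


def _topog1(record) -> bool:
    text = _norm(record.diagnosis_text)
    return any(_T2.match(c) for c in record.topography_codes) or bool(
        _LUNG_KW.search(text)
    )


def first_version_oracle(record) -> bool:
    return _morpho1(record) and _topog1(record)


def first_modification_oracle(record) -> bool:
    return (
        _morpho1(record)
        and not any(_NEURO.match(c) for c in record.morphology_codes)
        and _topog1(record)
        and not any(
            _UPPER.match(c) or _RESP_NOS.match(c) for c in record.topography_codes
        )
    )


def second_modification_oracle(record) -> bool:
    return (
        _morpho1(record)
        and not any(_NEURO.match(c) for c in record.morphology_codes)
        and _topog1(record)
        and not any(_UPPER.match(c) for c in record.topography_codes)
    )


ALGORITHM_ORACLES = {
    "first_version": first_version_oracle,
    "first_modification": first_modification_oracle,
    "second_modification": second_modification_oracle,
}


def kappa_oracle(ratings_a, ratings_b):
    """Cohen's kappa from first principles: explicit po/pe loops.

    Returns None when chance agreement is 1 (both raters constant, equal).
    """
    n = len(ratings_a)
    categories = sorted(set(ratings_a) | set(ratings_b))
    po = sum(1 for x, y in zip(ratings_a, ratings_b) if x == y) / n
    pe = 0.0
    for c in categories:
        pa = sum(1 for x in ratings_a if x == c) / n
        pb = sum(1 for y in ratings_b if y == c) / n
        pe += pa * pb
    if pe >= 1.0 - 1e-12:
        return None
    return (po - pe) / (1.0 - pe)
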