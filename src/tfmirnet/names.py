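"""miRNA identifier normalisation.

miRBase names multi-copy miRNA genes by appending a genomic-copy index to the
transcript name: ``hsa-let-7a-1``, ``hsa-let-7a-2`` and ``hsa-let-7a-3`` all
produce the same mature ``hsa-let-7a``.  Expression platforms and target
libraries disagree on whether they carry the copy index, so every identifier
entering this package is consolidated to its *root form* first.
"""

from __future__ import annotations

import re

__all__ = ["consolidate_mirna_name", "looks_like_mirna"]

# A trailing "-<digits>" group is a genomic-copy index only when the token in
# front of it already carries the miR number (ends in digits plus optional
# family letters, e.g. "7a", "125b", "17").  In "hsa-miR-1" the "-1" IS the
# miR number (the preceding token "miR" has no digits), so it is kept.
_COPY_SUFFIX = re.compile(r"^(?P<stem>.*\d[A-Za-z]*)-(?P<copy>\d+)$")

_MIRNA_LIKE = re.compile(r"^[A-Za-z]{3,4}-(let|mir)-", re.IGNORECASE)


def consolidate_mirna_name(name: str) -> str:
    """Strip a genomic-copy index suffix from a miRNA transcript name.

    Arm suffixes (``-3p``/``-5p``) and lettered family suffixes are preserved;
    names without a copy index are returned unchanged.  The function is
    idempotent.

    >>> consolidate_mirna_name("hsa-let-7a-1")
    'hsa-let-7a'
    >>> consolidate_mirna_name("hsa-miR-1")
    'hsa-miR-1'
    >>> consolidate_mirna_name("hsa-miR-17-5p")
    'hsa-miR-17-5p'
    """
    if not name:
        raise ValueError("empty miRNA name")
    m = _COPY_SUFFIX.match(name)
    if m:
        return m.group("stem")
    return name


def looks_like_mirna(name: str) -> bool:
    """Heuristic test for miRBase-style transcript names (``hsa-miR-…``).

    Used only to catch type-rule violations (e.g. a miRNA appearing as a
    target inside a miRNA->gene library); gene symbols never match.
    """
    return bool(_MIRNA_LIKE.match(name))
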