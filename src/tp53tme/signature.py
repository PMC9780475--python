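"""TP53 activity gene signature: the 20 induced / 10 repressed target genes.

The signature splits direct transcriptional targets of p53 into genes it
induces (DNA-damage response, apoptosis: DDB2, FAS, GADD45A, ...) and genes
it represses (cell-cycle drivers: CCNB1, PLK1, CDK1, ...).  A sample with
functional p53 expresses the induced set highly and the repressed set lowly;
the activity score built downstream is the enrichment of the first minus the
enrichment of the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

DEFAULT = "default"
_VALID_DIRECTIONS = {"induced", "repressed"}


class SignatureError(ValueError):
    """Raised when a gene signature violates its invariants."""


@dataclass(frozen=True)
class GeneSignature:
    """Two disjoint, ordered gene sets defining a transcriptional signature.

    Parameters
    ----------
    induced : tuple of str
        Symbols up-regulated when the pathway is active.
    repressed : tuple of str
        Symbols down-regulated when the pathway is active.
    name : str
        Free-text label.
    """

    induced: tuple[str, ...]
    repressed: tuple[str, ...]
    name: str = "signature"

    def __post_init__(self) -> None:
        for label, genes in (("induced", self.induced), ("repressed", self.repressed)):
            if len(genes) == 0:
                raise SignatureError(f"{label} gene set is empty")
            seen: set[str] = set()
            for g in genes:
                if g in seen:
                    raise SignatureError(f"duplicate symbol in {label} set: {g}")
                seen.add(g)
        overlap = set(self.induced) & set(self.repressed)
        if overlap:
            raise SignatureError(
                "symbols present in both induced and repressed sets: "
                + ", ".join(sorted(overlap))
            )

    @property
    def genes(self) -> tuple[str, ...]:
        """All signature symbols, induced first."""
        return self.induced + self.repressed

    def __len__(self) -> int:
        return len(self.induced) + len(self.repressed)


def _parse_signature_lines(lines: list[str], name: str) -> GeneSignature:
    induced: list[str] = []
    repressed: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.replace(",", "\t").split("\t")
        if len(parts) < 2:
            raise SignatureError(
                f"line {lineno}: expected two columns (symbol, direction), got {line!r}"
            )
        symbol, direction = parts[0].strip(), parts[1].strip().lower()
        if lineno == 1 and symbol.lower() in ("symbol", "gene"):
            continue  # header row
        if direction not in _VALID_DIRECTIONS:
            raise SignatureError(
                f"line {lineno}: direction must be one of {sorted(_VALID_DIRECTIONS)}, "
                f"got {direction!r}"
            )
        (induced if direction == "induced" else repressed).append(symbol)
    return GeneSignature(tuple(induced), tuple(repressed), name=name)


def load_signature(path_or_default: Union[str, Path] = DEFAULT) -> GeneSignature:
    """Load a two-column (symbol, direction) signature file.

    Passing the sentinel ``"default"`` returns the packaged TP53 activity
    signature: 20 induced and 10 repressed p53 target genes.

    Raises
    ------
    SignatureError
        On duplicate symbols, overlap between the two sets, or an empty set.
    """
    if path_or_default == DEFAULT:
        text = (
            resources.files("tp53tme.data").joinpath("tp53_signature.tsv").read_text()
        )
        return _parse_signature_lines(text.splitlines(), name="TP53 activity")
    path = Path(path_or_default)
    return _parse_signature_lines(path.read_text().splitlines(), name=path.stem)
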