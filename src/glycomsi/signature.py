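"""Gene signatures: ordered up/down gene lists.

A :class:`GeneSignature` is the unit passed between the screen and the
scoring stage. The packaged default, :data:`GLYCO_MSI_V1`, is the
five-gene glycosyltransferase signature separating MSI from MSS
colorectal cancer: GALNT7, GALNT1 and HPSE up in MSI; GALNT6 and
ST6GAL1 down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class GeneSignature:
    """Ordered up-regulated and down-regulated gene lists.

    Parameters
    ----------
    up_genes
        Genes with higher expression in the positive (MSI) class.
    down_genes
        Genes with lower expression in the positive class.
    name
        Human-readable identifier carried through outputs.
    """

    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    name: str = "signature"

    def __post_init__(self) -> None:
        up = tuple(self.up_genes)
        down = tuple(self.down_genes)
        object.__setattr__(self, "up_genes", up)
        object.__setattr__(self, "down_genes", down)
        if set(up) & set(down):
            raise ValueError(
                f"genes in both arms: {sorted(set(up) & set(down))}"
            )
        if len(up) + len(down) == 0:
            raise ValueError("signature must contain at least one gene")
        if len(set(up)) != len(up) or len(set(down)) != len(down):
            raise ValueError("duplicate gene within a signature arm")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes

    def swapped(self) -> "GeneSignature":
        """Return the signature with up and down arms exchanged."""
        return GeneSignature(self.down_genes, self.up_genes, f"{self.name}_swapped")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"name": self.name, "up": list(self.up_genes), "down": list(self.down_genes)},
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneSignature":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["up"]), tuple(d["down"]), d.get("name", "signature"))


#: The packaged Glyco-MSI signature (three up, two down).
GLYCO_MSI_V1 = GeneSignature(
    up_genes=("GALNT7", "GALNT1", "HPSE"),
    down_genes=("GALNT6", "ST6GAL1"),
    name="glyco_msi_v1",
)
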