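"""Optional adapter: 1D/2D descriptor matrices from SMILES via RDKit.

The core pipeline consumes descriptor CSVs and never requires a
cheminformatics toolkit; this adapter is for users who want to produce the
per-species descriptor vectors themselves. RDKit is imported lazily.
"""
from __future__ import annotations

from typing import Sequence

import pandas as pd

from .exceptions import ValidationError

__all__ = ["compute_descriptors"]


def compute_descriptors(smiles: Sequence[str], ids: Sequence[str] | None = None) -> pd.DataFrame:
    """All RDKit 2D descriptors for each SMILES, one row per molecule."""
    try:
        from rdkit import Chem
        from rdkit.Chem import Descriptors
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "RDKit is required for descriptor computation from SMILES; "
            "install rdkit or supply descriptor CSVs directly"
        ) from exc

    if ids is None:
        ids = [f"M{i + 1:03d}" for i in range(len(smiles))]
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValidationError(f"unparsable SMILES: {smi!r}")
        rows.append(Descriptors.CalcMolDescriptors(mol))
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"))
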