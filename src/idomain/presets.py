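"""Residue-map presets for the two beta2-integrin alpha-I domains.

The numbers are data, not code: a config file may override any entry.
LFA-1 entries follow the residue identities used throughout the
structural literature for the alphaL I domain (alpha7 helix E293-K305,
zipper pairs F153-F292 and L161-F299, MIDAS loop residues D137, S139,
S141, T206, D239, E241, ligand carboxylate E34 of ICAM-1 domain D1).
Mac-1 (alphaM) entries use the standard 1IDO/1JLM numbering: MIDAS
residues D140, S142, S144, T209, D242 (S144 is the serine whose
side-chain orientation can cap the ion), zipper pairs F156-F302 and
L164-Q309, ligand carboxylate D229 of ICAM-1 domain D3; the alpha7
segment and core ranges are mapped from the LFA-1 ones by the zipper
residue offset and are meant to be overridden when author numbering of a
specific deposition differs.
"""

from __future__ import annotations

MOLECULE_PRESETS: dict[str, dict] = {
    "LFA-1": {
        "chain": "A",
        "alpha7": (293, 305),
        "zipper_pairs": [(153, 292), (161, 299)],
        "midas_candidates": [137, 139, 141, 206, 239, 241],
        "ligand_residue": ("B", 34),  # ICAM-1 D1 Glu34
        "core_ranges": [(170, 200), (250, 280)],
    },
    "Mac-1": {
        "chain": "A",
        "alpha7": (303, 315),
        "zipper_pairs": [(156, 302), (164, 309)],
        "midas_candidates": [140, 142, 144, 209, 242],
        "ligand_residue": ("B", 229),  # ICAM-1 D3 Asp229
        "core_ranges": [(180, 210), (260, 290)],
    },
}


def molecule_preset(name: str) -> dict:
    try:
        return dict(MOLECULE_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown molecule preset {name!r}; available: {sorted(MOLECULE_PRESETS)}"
        ) from None
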