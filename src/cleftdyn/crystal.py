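"""Reference metrics computed directly from a crystal structure.

For the YqhD holoenzyme entry (PDB 1OJ7) these reproduce the published
crystal-structure values: dimer radius of gyration 2.71 nm, monomer-D
radius of gyration 2.07 nm and a D159–H363 cleft minimum distance of
0.16 nm (closed cleft).  The PDB file itself must be supplied by the
caller (e.g. downloaded from the RCSB); nothing here requires it to be
that particular entry.
"""

from __future__ import annotations

from pathlib import Path

from .geometry import min_distance, radius_of_gyration
from .structio import Structure, Trajectory, read_pdb, select

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch_pdb(pdb_id: str, dest: str | Path, timeout: float = 30.0) -> Path:
    """Download a PDB entry from the RCSB into ``dest`` (skips if present)."""
    import urllib.request

    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    path = dest / f"{pdb_id.upper()}.pdb"
    if not path.exists():
        with urllib.request.urlopen(
            RCSB_URL.format(pdb_id=pdb_id.upper()), timeout=timeout
        ) as resp:
            path.write_bytes(resp.read())
    return path


def crystal_report(
    pdb_path: str | Path,
    *,
    monomer_chain: str = "D",
    dimer_chains: tuple[str, str] = ("A", "D"),
    cleft_pair: tuple[int, int] = (159, 363),
) -> dict[str, float]:
    """Rg of the dimer and one monomer plus the cleft minimum distance, nm.

    The monomer defaults to chain D (the Zn-bearing monomer of 1OJ7); all
    values are over protein atoms, mass weighted.
    """
    s = read_pdb(pdb_path)
    if isinstance(s, Trajectory):
        s = s.frame_structure(0)
    assert isinstance(s, Structure)
    dimer = select(s, f"protein and (chain {dimer_chains[0]} or chain {dimer_chains[1]})")
    monomer = select(s, f"protein and chain {monomer_chain}")
    res_a = select(s, f"chain {monomer_chain} and resid {cleft_pair[0]}")
    res_b = select(s, f"chain {monomer_chain} and resid {cleft_pair[1]}")
    return {
        "dimer_rg_nm": radius_of_gyration(
            s.coords[dimer.indices], s.masses[dimer.indices]
        ),
        "monomer_rg_nm": radius_of_gyration(
            s.coords[monomer.indices], s.masses[monomer.indices]
        ),
        "cleft_min_distance_nm": min_distance(res_a, res_b, s.coords),
    }
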