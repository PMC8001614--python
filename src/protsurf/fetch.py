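"""Locate deposited coordinate files: local cache first, then RCSB.

Real entries are inputs to the analysis, not package data; they are looked up
in local cache directories and, failing that, downloaded from the RCSB file
server. Both steps may legitimately fail on an offline machine, in which case
:class:`FetchError` reports what was tried.
"""

from __future__ import annotations

import gzip
import shutil
import urllib.error
import urllib.request
from pathlib import Path

from .errors import FetchError

_RCSB_URL = "https://files.rcsb.org/download/{entry}.cif.gz"
_DEFAULT_CACHE_DIRS = ("scratch/structures", "data/structures")


def fetch_structure(
    entry_id: str,
    cache_dirs: tuple[str, ...] = _DEFAULT_CACHE_DIRS,
    timeout: float = 15.0,
) -> Path:
    """Return a path to the mmCIF (or PDB) file for ``entry_id``.

    Searches each cache directory for ``<entry>.cif``, ``<entry>.cif.gz`` or
    ``<entry>.pdb`` (case-insensitive), then attempts a download into the
    first cache directory. Raises :class:`FetchError` if neither works.
    """
    entry = entry_id.upper()
    names = [
        f"{e}{ext}"
        for e in (entry, entry.lower())
        for ext in (".cif", ".cif.gz", ".pdb", ".pdb.gz")
    ]
    for d in cache_dirs:
        for name in names:
            p = Path(d) / name
            if p.exists():
                return _maybe_decompress(p)
    target_dir = Path(cache_dirs[0])
    target_dir.mkdir(parents=True, exist_ok=True)
    gz_path = target_dir / f"{entry}.cif.gz"
    url = _RCSB_URL.format(entry=entry)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp, open(gz_path, "wb") as fh:
            shutil.copyfileobj(resp, fh)
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchError(
            f"entry {entry} not found in {list(cache_dirs)} and download from "
            f"{url} failed ({exc}); place the file in one of the cache directories"
        ) from exc
    return _maybe_decompress(gz_path)


def _maybe_decompress(path: Path) -> Path:
    if path.suffix != ".gz":
        return path
    out = path.with_suffix("")
    if not out.exists():
        with gzip.open(path, "rb") as src, open(out, "wb") as dst:
            shutil.copyfileobj(src, dst)
    return out
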