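"""Submission bundles: checksummed BagIt-style archives with provenance.

A submitter runs a lightweight structural validation locally, then packs
the TSVs, a copy of the schema descriptor, and minimal provenance (DCC id,
toolkit version, creation timestamp) into a BagIt-layout zip: payload under
``data/``, a SHA-256 manifest, and bag metadata in ``bag-info.txt``.  Deep
validation happens again at ingest, mirroring the two-stage flow; since the
deep checks are a superset, anything that passes ingest would have bundled.
Timestamps are injected parameters, so a bundle is a deterministic function
of its inputs.
"""

from __future__ import annotations

import hashlib
import zipfile
from pathlib import Path

from . import errors, validate as validate_mod
from .errors import C2M2Error

CHECKSUM = "sha256"
_FIXED_EPOCH = (1980, 1, 1, 0, 0, 0)   # zip timestamps are not provenance


def _sha256(data):
    return hashlib.sha256(data).hexdigest()


def bundle(package_dir, dcc, out_path, registry, *, toolkit_version="0.1.0",
           timestamp="1970-01-01T00:00:00Z"):
    """Pack a package directory into a verified archive.

    Raises a BAD_BUNDLE error carrying the report when the lightweight
    validation (file inventory, headers, rows, keys) fails.  Returns the
    archive path.
    """
    package_dir = Path(package_dir)
    _, report = validate_mod.lightweight_validate(package_dir, registry)
    if not report.valid:
        raise C2M2Error(errors.BAD_BUNDLE,
                        "package failed lightweight validation; not bundling",
                        report=report)

    payload = {}
    for name in registry.list_tables():
        payload[f"data/{name}.tsv"] = (package_dir / f"{name}.tsv").read_bytes()
    descriptor = package_dir / "datapackage.json"
    if descriptor.exists():
        payload["data/datapackage.json"] = descriptor.read_bytes()
    else:
        registry.write_descriptor(package_dir / "datapackage.json")
        payload["data/datapackage.json"] = (
            package_dir / "datapackage.json").read_bytes()

    manifest = "".join(
        f"{_sha256(data)}  {arcname}\n"
        for arcname, data in sorted(payload.items()))
    bag_info = (
        f"Bag-Software-Agent: c2m2-toolkit {toolkit_version}\n"
        f"Bagging-Timestamp: {timestamp}\n"
        f"C2M2-Schema-Version: {registry.version}\n"
        f"Source-Organization: {dcc}\n"
    )
    tag_files = {
        "bagit.txt": b"BagIt-Version: 1.0\nTag-File-Character-Encoding: UTF-8\n",
        "bag-info.txt": bag_info.encode(),
        f"manifest-{CHECKSUM}.txt": manifest.encode(),
    }
    tagmanifest = "".join(
        f"{_sha256(data)}  {name}\n" for name, data in sorted(tag_files.items()))
    tag_files[f"tagmanifest-{CHECKSUM}.txt"] = tagmanifest.encode()

    out_path = Path(out_path)
    with zipfile.ZipFile(out_path, "w", compression=zipfile.ZIP_STORED) as zf:
        for arcname in sorted({**tag_files, **payload}):
            data = tag_files.get(arcname, payload.get(arcname))
            info = zipfile.ZipInfo(arcname, date_time=_FIXED_EPOCH)
            zf.writestr(info, data)
    return out_path


def verify_bundle(path):
    """Recompute every payload checksum.  Returns ``(ok, bad_files)``.

    ``bad_files`` names exactly the archive members whose checksum differs
    from (or is missing from) the manifest.
    """
    bad = []
    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        manifest_name = f"manifest-{CHECKSUM}.txt"
        if manifest_name not in names:
            return False, [manifest_name]
        expected = {}
        for line in zf.read(manifest_name).decode().splitlines():
            digest, arcname = line.split("  ", 1)
            expected[arcname] = digest
        for arcname, digest in sorted(expected.items()):
            if arcname not in names:
                bad.append(arcname)
            elif _sha256(zf.read(arcname)) != digest:
                bad.append(arcname)
        for arcname in sorted(names):
            if arcname.startswith("data/") and arcname not in expected:
                bad.append(arcname)
    return not bad, bad


def read_provenance(path):
    """The bag-info fields as a dict."""
    with zipfile.ZipFile(path) as zf:
        text = zf.read("bag-info.txt").decode()
    out = {}
    for line in text.splitlines():
        key, _, value = line.partition(": ")
        out[key] = value
    return out


def unpack(path, directory):
    """Extract the payload back into a package directory (byte-for-byte)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path) as zf:
        for arcname in zf.namelist():
            if arcname.startswith("data/"):
                target = directory / arcname[len("data/"):]
                target.write_bytes(zf.read(arcname))
    return directory


def submit(store, bundle_path, refs=None, provisional=None, *,
           received_at="1970-01-01T00:00:00Z", workdir=None):
    """Verify, unpack, deep-validate and ingest a bundle.

    A tampered archive raises BAD_BUNDLE and nothing is ingested; an archive
    whose package fails deep validation is retained as a rejected
    submission.  Valid submissions are advanced to ``in-review`` — visible
    to the submitting DCC, absent from the public view until approved and
    released.
    """
    ok, bad = verify_bundle(bundle_path)
    if not ok:
        raise C2M2Error(errors.BAD_BUNDLE,
                        f"checksum verification failed for: {', '.join(bad)}")
    provenance = read_provenance(bundle_path)
    dcc = provenance.get("Source-Organization", "UNKNOWN")
    import tempfile
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        package_dir = unpack(bundle_path, Path(tmp) / "payload")
        sub = store.ingest(dcc, package_dir, refs, provisional,
                           received_at=received_at)
    if sub.status == "uploaded":
        store.review(sub)
    return sub
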