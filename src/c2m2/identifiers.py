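"""The two-part C2M2 identifier scheme and persistent-ID classification.

Every entity record carries a mandatory C2M2 ID made of an ``id_namespace``
prefix (owned by the submitting DCC, registered in advance) and a
``local_id`` suffix chosen freely by the DCC.  Concatenated, the two parts
form a key that can never collide across DCCs, because no two DCCs share a
namespace.  An optional persistent ID (DOI, minid, DRS URI, or any other
URI) may be attached alongside.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from . import errors
from .errors import C2M2Error

#: Separator used when concatenating the two ID parts.  It is forbidden in
#: namespace tokens, which makes the concatenation injective.
SEPARATOR = "|"

PERSISTENT_ID_SCHEMES = ("doi", "minid", "drs", "generic-uri")

_URI_RE = re.compile(r"[a-z][a-z0-9+.\-]*:\S+\Z", re.IGNORECASE)


@dataclass(frozen=True)
class IdNamespace:
    """A registered ID namespace owned by one DCC."""

    namespace: str
    owner_dcc: str = ""
    registered: bool = True


@dataclass(frozen=True)
class C2M2Id:
    id_namespace: str
    local_id: str

    @property
    def global_key(self):
        return make_global_key(self.id_namespace, self.local_id)


@dataclass(frozen=True)
class PersistentId:
    scheme: str
    value: str


@dataclass(frozen=True)
class IdentifierClass:
    name: str
    mandatory: bool
    description: str


def make_global_key(namespace, local_id):
    """Concatenate namespace and local id into the catalog-wide unique key.

    Accepts an :class:`IdNamespace` (must be registered) or a bare namespace
    token.  Injective over (namespace, local_id) pairs because the separator
    may not occur in namespace tokens.
    """
    if isinstance(namespace, IdNamespace):
        if not namespace.registered:
            raise C2M2Error(errors.NAMESPACE_UNREGISTERED,
                            f"namespace {namespace.namespace!r} is not registered")
        token = namespace.namespace
    else:
        token = namespace
    if not token:
        raise C2M2Error(errors.NAMESPACE_UNREGISTERED, "empty namespace")
    if SEPARATOR in token:
        raise C2M2Error(errors.NAMESPACE_UNREGISTERED,
                        f"namespace {token!r} contains the reserved "
                        f"separator {SEPARATOR!r}")
    if not local_id:
        raise C2M2Error(errors.BAD_LOCAL_ID, "empty local_id")
    return f"{token}{SEPARATOR}{local_id}"


def classify_persistent_id(text):
    """Assign one scheme to a persistent-ID string by prefix/pattern.

    Recognises DOIs (``doi:`` or doi.org URLs), DRS URIs (``drs://``),
    minids (``minid:`` or ARK-style), and otherwise any URI-shaped string as
    ``generic-uri``.  Non-URI text raises BAD_PERSISTENT_ID.  Each input is
    assigned at most one scheme (first match wins, most specific first).
    """
    if not text or not text.strip():
        raise C2M2Error(errors.BAD_PERSISTENT_ID, "empty persistent id")
    lowered = text.lower()
    if lowered.startswith(("doi:", "https://doi.org/", "http://doi.org/",
                           "https://dx.doi.org/", "http://dx.doi.org/")):
        return PersistentId("doi", text)
    if lowered.startswith("drs://"):
        return PersistentId("drs", text)
    if lowered.startswith(("minid:", "ark:")):
        return PersistentId("minid", text)
    if _URI_RE.match(text):
        return PersistentId("generic-uri", text)
    raise C2M2Error(errors.BAD_PERSISTENT_ID,
                    f"{text!r} is neither a URI nor a recognised compact id")


def identifier_classes():
    """The identifier classes an entity record can carry (always two)."""
    return [
        IdentifierClass(
            name="c2m2_id", mandatory=True,
            description="Two-part ID: id_namespace prefix + local_id suffix; "
                        "concatenated they are unique across the catalog."),
        IdentifierClass(
            name="persistent_id", mandatory=False,
            description="Resolvable URI (DOI, minid, DRS, or generic) stored "
                        "separately from the C2M2 ID."),
    ]
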