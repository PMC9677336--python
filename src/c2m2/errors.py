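"""Error codes and the toolkit exception type.

Every failure mode surfaced by the toolkit carries one code from the closed
set below, so callers (and the validator, which reports the same codes as
issues instead of raising) can dispatch on machine-readable identifiers.
"""

from __future__ import annotations

# Validation issue codes (closed set; the validator emits exactly these).
MISSING_TABLE = "MISSING_TABLE"
BAD_HEADER = "BAD_HEADER"
BAD_ROW = "BAD_ROW"
MISSING_VALUE = "MISSING_VALUE"
DUPLICATE_PK = "DUPLICATE_PK"
FK_VIOLATION = "FK_VIOLATION"
MISSING_REQUIRED_RECORD = "MISSING_REQUIRED_RECORD"
ORPHAN_ENTITY = "ORPHAN_ENTITY"
NAMESPACE_UNREGISTERED = "NAMESPACE_UNREGISTERED"
UNKNOWN_TERM = "UNKNOWN_TERM"
WRONG_VOCABULARY = "WRONG_VOCABULARY"
TERM_TABLE_MISMATCH = "TERM_TABLE_MISMATCH"

#: Codes a validation issue may carry, in the order checks run.
VALIDATION_CODES = (
    MISSING_TABLE,
    BAD_HEADER,
    BAD_ROW,
    MISSING_VALUE,
    DUPLICATE_PK,
    FK_VIOLATION,
    MISSING_REQUIRED_RECORD,
    ORPHAN_ENTITY,
    NAMESPACE_UNREGISTERED,
    UNKNOWN_TERM,
    WRONG_VOCABULARY,
    TERM_TABLE_MISMATCH,
)

# Non-validation operational codes.
UNKNOWN_TABLE = "UNKNOWN_TABLE"
BAD_LOCAL_ID = "BAD_LOCAL_ID"
BAD_PERSISTENT_ID = "BAD_PERSISTENT_ID"
BAD_FACET = "BAD_FACET"
BAD_COMPARISON = "BAD_COMPARISON"
BAD_BUNDLE = "BAD_BUNDLE"
BAD_CONFIG = "BAD_CONFIG"


class C2M2Error(Exception):
    """Exception carrying a machine-readable ``code`` plus optional context.

    ``table``, ``row`` (1-based line number in the TSV file, counting the
    header as line 1) and ``field`` locate the offending cell when known.
    """

    def __init__(self, code, message, *, table=None, row=None, field=None,
                 report=None):
        super().__init__(f"{code}: {message}")
        self.code = code
        self.message = message
        self.table = table
        self.row = row
        self.field = field
        self.report = report
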