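"""Self-describing model archives.

A trained predictor is persisted as a single zip holding a JSON manifest
(format version, task, label domain, descriptor and predictor
configuration, seeds) plus a pickled payload with the fitted components.
Predictions after a save/load round trip are identical to pre-save
predictions. The format version is checked on load.
"""

from __future__ import annotations

import io
import json
import pickle
import zipfile

ARCHIVE_VERSION = 1


class ArchiveError(RuntimeError):
    pass


def save_model(
    path: str,
    model,
    vocabulary=None,
    task: str | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a predictor (and optional signature vocabulary) to a zip archive."""
    manifest = {
        "format_version": ARCHIVE_VERSION,
        "task": task,
        "model_class": type(model).__name__,
        "params": _jsonable(model.get_params()) if hasattr(model, "get_params") else {},
        "label_domain": [str(c) for c in getattr(model, "classes_", [])],
        "has_vocabulary": vocabulary is not None,
        "metadata": metadata or {},
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2, default=str))
        zf.writestr("model.pkl", pickle.dumps(model))
        if vocabulary is not None:
            buf = io.StringIO()
            for text, idx in sorted(vocabulary.index.items(), key=lambda kv: kv[1]):
                buf.write(f"{idx}\t{text}\n")
            zf.writestr("vocabulary.tsv", buf.getvalue())
            zf.writestr(
                "vocabulary_meta.json",
                json.dumps({
                    "h_min": vocabulary.h_min,
                    "h_max": vocabulary.h_max,
                    "extra_columns": vocabulary.extra_columns,
                }),
            )


def load_model(path: str):
    """Load (model, vocabulary_or_None, manifest) from an archive."""
    from .signatures import SignatureVocabulary

    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        version = manifest.get("format_version")
        if version != ARCHIVE_VERSION:
            raise ArchiveError(
                f"incompatible archive format version {version} (expected {ARCHIVE_VERSION})"
            )
        model = pickle.loads(zf.read("model.pkl"))
        vocabulary = None
        if manifest.get("has_vocabulary"):
            meta = json.loads(zf.read("vocabulary_meta.json"))
            vocabulary = SignatureVocabulary(h_min=meta["h_min"], h_max=meta["h_max"])
            vocabulary.extra_columns = meta.get("extra_columns", [])
            for line in zf.read("vocabulary.tsv").decode().splitlines():
                idx_s, _, text = line.partition("\t")
                vocabulary.index[text] = int(idx_s)
    return model, vocabulary, manifest


def _jsonable(obj):
    try:
        json.dumps(obj)
        return obj
    except TypeError:
        if isinstance(obj, dict):
            return {k: _jsonable(v) for k, v in obj.items()}
        return repr(obj)
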