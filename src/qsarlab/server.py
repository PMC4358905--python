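"""Minimal JSON-over-HTTP prediction endpoint (stdlib only).

GET  /models  -> JSON list of published version metadata
POST /predict -> {"tag": ..., "version": ..., "sdf": "<sdf text>"}
                 returns a JSON list of prediction-result objects

Confidential models are served identically, with ``adan_category`` "NA".
"""

from __future__ import annotations

import json
import math
import tempfile
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path

from . import store, workflows

__all__ = ["make_server", "run_server"]


def _json_safe(obj):
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_json_safe(v) for v in obj]
    return obj


class _Handler(BaseHTTPRequestHandler):
    root: str = "./models"

    def log_message(self, *args):  # quiet
        pass

    def _send(self, code: int, payload) -> None:
        body = json.dumps(_json_safe(payload)).encode("utf-8")
        self.send_response(code)
        self.send_header("Content-Type", "application/json; charset=utf-8")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def do_GET(self):
        if self.path.rstrip("/") != "/models":
            self._send(404, {"error": "not found"})
            return
        out = []
        root = Path(self.root)
        if root.is_dir():
            for tag_dir in sorted(root.iterdir()):
                if not tag_dir.is_dir():
                    continue
                try:
                    metas = store.list_versions(self.root, tag_dir.name)
                except FileNotFoundError:
                    continue
                out.extend(m.__dict__ for m in metas if m.version > 0)
        self._send(200, out)

    def do_POST(self):
        if self.path.rstrip("/") != "/predict":
            self._send(404, {"error": "not found"})
            return
        try:
            length = int(self.headers.get("Content-Length", "0"))
            payload = json.loads(self.rfile.read(length).decode("utf-8"))
            tag = payload["tag"]
            version = int(payload["version"])
            sdf_text = payload["sdf"]
        except (json.JSONDecodeError, KeyError, ValueError, UnicodeDecodeError):
            self._send(400, {"error": "malformed request body"})
            return
        try:
            store.load_version(self.root, tag, version)
        except FileNotFoundError:
            self._send(404, {"error": f"unknown model {tag} version {version}"})
            return
        try:
            with tempfile.NamedTemporaryFile("w", suffix=".sdf", delete=False) as fh:
                fh.write(sdf_text)
                sdf_path = fh.name
            try:
                results = workflows.predict_workflow(self.root, tag, version, sdf_path)
            finally:
                Path(sdf_path).unlink(missing_ok=True)
        except ValueError as exc:
            self._send(400, {"error": str(exc)})
            return
        self._send(200, [r.to_dict() for r in results])


def make_server(root, host: str = "127.0.0.1", port: int = 0) -> ThreadingHTTPServer:
    handler = type("BoundHandler", (_Handler,), {"root": str(root)})
    return ThreadingHTTPServer((host, port), handler)


def run_server(root, host: str = "127.0.0.1", port: int = 8220) -> None:
    server = make_server(root, host, port)
    print(f"serving model repository {root} on http://{host}:{server.server_address[1]}")
    try:
        server.serve_forever()
    except KeyboardInterrupt:
        server.shutdown()
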