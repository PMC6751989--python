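"""HTTP endpoints over the ingest server, and the matching client transport.

A deliberately small JSON-over-HTTP surface (stdlib ``http.server`` and
``urllib``; no web framework):

* ``POST /ingest``  — body is the transmission-batch wire JSON; response is
  the acknowledgement JSON.
* ``GET /series?device=...&t0=...&t1=...``  — interchange CSV of the held
  records in the half-open window.
* ``GET /gaps?device=...&t0=...&t1=...``  — JSON list of missing-minute runs.

Timestamps in query strings are ISO-8601.  The client-side
:class:`HttpTransport` enforces its timeout via the socket timeout.
"""

from __future__ import annotations

import io
import json
import threading
import urllib.error
import urllib.parse
import urllib.request
from datetime import datetime
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .protocol import CSV_HEADER, floor_to_minute
from .server import IngestServer
from .telemetry import Ack, TransmissionBatch, TransportError, TransportTimeout


def _ack_to_json(ack: Ack) -> bytes:
    doc = {
        "accepted": [t.strftime("%Y-%m-%dT%H:%M:%SZ") for t in ack.accepted],
        "duplicate": [t.strftime("%Y-%m-%dT%H:%M:%SZ") for t in ack.duplicate],
        "rejected": [t.strftime("%Y-%m-%dT%H:%M:%SZ") for t in ack.rejected],
        "error": ack.error,
    }
    return json.dumps(doc).encode()


def _ack_from_json(data: bytes) -> Ack:
    doc = json.loads(data)
    parse = lambda ts: floor_to_minute(datetime.fromisoformat(ts))
    return Ack(
        accepted=tuple(parse(t) for t in doc.get("accepted", ())),
        duplicate=tuple(parse(t) for t in doc.get("duplicate", ())),
        rejected=tuple(parse(t) for t in doc.get("rejected", ())),
        error=doc.get("error"),
    )


def make_http_server(server: IngestServer, host: str = "127.0.0.1", port: int = 0) -> ThreadingHTTPServer:
    """Bind the ingest server to an HTTP listener (port 0 = ephemeral)."""

    class Handler(BaseHTTPRequestHandler):
        def log_message(self, fmt, *args):  # quiet by default
            pass

        def _reply(self, code: int, body: bytes, ctype: str = "application/json") -> None:
            self.send_response(code)
            self.send_header("Content-Type", ctype)
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def do_POST(self) -> None:
            if self.path != "/ingest":
                self._reply(404, b'{"error": "not found"}')
                return
            length = int(self.headers.get("Content-Length", "0"))
            ack = server.ingest_payload(self.rfile.read(length))
            self._reply(200, _ack_to_json(ack))

        def do_GET(self) -> None:
            parsed = urllib.parse.urlparse(self.path)
            q = urllib.parse.parse_qs(parsed.query)
            try:
                device = q["device"][0]
                t0 = floor_to_minute(datetime.fromisoformat(q["t0"][0]))
                t1 = floor_to_minute(datetime.fromisoformat(q["t1"][0]))
            except (KeyError, ValueError):
                self._reply(400, b'{"error": "device, t0, t1 query params required"}')
                return
            if parsed.path == "/series":
                buf = io.StringIO()
                buf.write(CSV_HEADER + "\n")
                for r in server.query_series(device, t0, t1):
                    buf.write(
                        f"{r.timestamp.strftime('%Y-%m-%dT%H:%M:%SZ')},"
                        f"{r.small_count},{r.large_count}\n"
                    )
                self._reply(200, buf.getvalue().encode(), "text/csv")
            elif parsed.path == "/gaps":
                runs = server.gap_report(device, t0, t1)
                doc = [
                    {
                        "start": g.start.strftime("%Y-%m-%dT%H:%M:%SZ"),
                        "length_min": g.length_min,
                    }
                    for g in runs
                ]
                self._reply(200, json.dumps(doc).encode())
            else:
                self._reply(404, b'{"error": "not found"}')

    return ThreadingHTTPServer((host, port), Handler)


def serve_in_thread(server: IngestServer, host: str = "127.0.0.1", port: int = 0) -> tuple[ThreadingHTTPServer, str]:
    """Start the HTTP listener on a daemon thread; returns (httpd, base_url)."""
    httpd = make_http_server(server, host, port)
    t = threading.Thread(target=httpd.serve_forever, daemon=True)
    t.start()
    return httpd, f"http://{httpd.server_address[0]}:{httpd.server_address[1]}"


class HttpTransport:
    """Deliver batches to a remote ingest endpoint over HTTP POST."""

    def __init__(self, base_url: str):
        self.base_url = base_url.rstrip("/")

    def send(self, batch: TransmissionBatch, timeout_s: float) -> Ack:
        req = urllib.request.Request(
            self.base_url + "/ingest",
            data=batch.to_payload().encode(),
            headers={"Content-Type": "application/json"},
            method="POST",
        )
        try:
            with urllib.request.urlopen(req, timeout=timeout_s) as resp:
                return _ack_from_json(resp.read())
        except TimeoutError as exc:
            raise TransportTimeout(str(exc)) from exc
        except (urllib.error.URLError, OSError) as exc:
            if isinstance(getattr(exc, "reason", None), TimeoutError):
                raise TransportTimeout(str(exc)) from exc
            raise TransportError(str(exc)) from exc
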