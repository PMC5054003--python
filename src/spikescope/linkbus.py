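"""Publish/subscribe protocol linking the temporal, spatial and structural
views: selection, play-head, playback-control and camera events.

Messages are canonical JSON (UTF-8, sorted keys, no insignificant
whitespace) prefixed by the topic name and a newline, so any two processes
serialize a given message to identical bytes. Four topics are defined:

``selection``  {"name": str, "gids": [ints]} — full gid lists, not deltas
``frame``      {"time_ms": number} — the shared play-head
``playback``   {"op": "play"|"pause"|"stop"|"goto_begin"|"loop_on"|"loop_off"}
``camera``     {"view": [16 reals, column-major]}

Transport is plain TCP with explicit endpoints: a small broker fans
length-prefixed frames out to subscribers, preserves per-publisher order,
and retains the latest message per topic so late joiners immediately
receive the current selection / play-head / camera state (all payloads are
full-state and therefore idempotent).
"""

from __future__ import annotations

import json
import socket
import struct
import threading
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

__all__ = [
    "TOPICS",
    "PLAYBACK_OPS",
    "BusError",
    "UnknownTopicError",
    "SchemaError",
    "TruncatedError",
    "BusMessage",
    "serialize",
    "deserialize",
    "PlaybackState",
    "apply_playback",
    "tick",
    "Broker",
    "Publisher",
    "Subscriber",
]

TOPICS = ("selection", "frame", "playback", "camera")
PLAYBACK_OPS = ("play", "pause", "stop", "goto_begin", "loop_on", "loop_off")


class BusError(Exception):
    """Base class for bus protocol errors."""


class UnknownTopicError(BusError):
    pass


class SchemaError(BusError):
    pass


class TruncatedError(BusError):
    pass


def _is_real(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def _validate_payload(topic: str, payload) -> None:
    if not isinstance(payload, dict):
        raise SchemaError(f"{topic}: payload must be an object")
    if topic == "selection":
        if set(payload) != {"name", "gids"}:
            raise SchemaError("selection payload needs exactly 'name' and 'gids'")
        if not isinstance(payload["name"], str) or not payload["name"]:
            raise SchemaError("selection name must be a non-empty string")
        gids = payload["gids"]
        if not isinstance(gids, list) or not all(
            isinstance(g, int) and not isinstance(g, bool) and g >= 0 for g in gids
        ):
            raise SchemaError("selection gids must be a list of non-negative ints")
    elif topic == "frame":
        if set(payload) != {"time_ms"} or not _is_real(payload["time_ms"]):
            raise SchemaError("frame payload needs a numeric 'time_ms'")
    elif topic == "playback":
        if set(payload) != {"op"} or payload["op"] not in PLAYBACK_OPS:
            raise SchemaError(f"playback op must be one of {PLAYBACK_OPS}")
    elif topic == "camera":
        view = payload.get("view")
        if set(payload) != {"view"} or not isinstance(view, list) or len(view) != 16 \
                or not all(_is_real(v) for v in view):
            raise SchemaError("camera payload needs 'view': 16 reals (column-major)")
    else:
        raise UnknownTopicError(f"unknown topic {topic!r}")


@dataclass(frozen=True)
class BusMessage:
    """A typed bus event: topic, per-publisher monotone sequence number, and
    a topic-specific payload."""

    topic: str
    seq: int
    payload: dict

    def __post_init__(self) -> None:
        if self.topic not in TOPICS:
            raise UnknownTopicError(f"unknown topic {self.topic!r}")
        _validate_payload(self.topic, self.payload)


def serialize(msg: BusMessage) -> bytes:
    """Topic prefix + newline + canonical JSON; bit-exact across processes."""
    body = json.dumps(
        {"payload": msg.payload, "seq": msg.seq, "topic": msg.topic},
        sort_keys=True,
        separators=(",", ":"),
        ensure_ascii=False,
    )
    return msg.topic.encode() + b"\n" + body.encode()


def deserialize(data: bytes) -> BusMessage:
    if b"\n" not in data:
        raise TruncatedError("missing topic prefix / newline")
    prefix, body = data.split(b"\n", 1)
    topic = prefix.decode("utf-8", errors="replace")
    if topic not in TOPICS:
        raise UnknownTopicError(f"unknown topic {topic!r}")
    if not body:
        raise TruncatedError("empty message body")
    try:
        obj = json.loads(body.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise TruncatedError(f"undecodable message body: {exc}") from exc
    if not isinstance(obj, dict) or set(obj) != {"payload", "seq", "topic"}:
        raise SchemaError("message must have exactly payload, seq, topic")
    if obj["topic"] != topic:
        raise SchemaError("topic prefix does not match body topic")
    if not isinstance(obj["seq"], int) or isinstance(obj["seq"], bool):
        raise SchemaError("seq must be an integer")
    return BusMessage(topic=topic, seq=obj["seq"], payload=obj["payload"])


# ---------------------------------------------------------------------------
# playback state machine


@dataclass(frozen=True)
class PlaybackState:
    """Shared playback state: the play-head (ms) within a window, a playing
    flag and a looping flag."""

    playhead: float
    playing: bool = False
    looping: bool = False
    t_start: float = 0.0
    t_end: float = 0.0

    def __post_init__(self) -> None:
        if not self.t_start <= self.playhead <= self.t_end:
            raise SchemaError("playhead outside the playback window")


def apply_playback(state: PlaybackState, msg: BusMessage) -> PlaybackState:
    """Apply a playback or frame message.

    play/pause toggle the playing flag; stop also rewinds; goto_begin
    rewinds but keeps playing; loop_on/off set looping; a frame message
    moves the play-head, clamped into the window.
    """
    if msg.topic == "frame":
        t = float(msg.payload["time_ms"])
        return replace(state, playhead=min(max(t, state.t_start), state.t_end))
    if msg.topic != "playback":
        return state
    op = msg.payload["op"]
    if op == "play":
        return replace(state, playing=True)
    if op == "pause":
        return replace(state, playing=False)
    if op == "stop":
        return replace(state, playing=False, playhead=state.t_start)
    if op == "goto_begin":
        return replace(state, playhead=state.t_start)
    if op == "loop_on":
        return replace(state, looping=True)
    if op == "loop_off":
        return replace(state, looping=False)
    raise SchemaError(f"unknown playback op {op!r}")


def tick(state: PlaybackState, dt: float) -> PlaybackState:
    """Advance a playing state by ``dt`` ms; wraps modularly past the end
    when looping, otherwise parks at the end and stops."""
    if not state.playing or dt <= 0:
        return state
    t = state.playhead + dt
    if t <= state.t_end:
        return replace(state, playhead=t)
    span = state.t_end - state.t_start
    if state.looping and span > 0:
        over = (t - state.t_start) % span
        return replace(state, playhead=state.t_start + over)
    return replace(state, playhead=state.t_end, playing=False)


# ---------------------------------------------------------------------------
# TCP transport

_LEN = struct.Struct(">I")


def _send_frame(sock: socket.socket, data: bytes) -> None:
    sock.sendall(_LEN.pack(len(data)) + data)


def _recv_exact(sock: socket.socket, n: int) -> bytes | None:
    buf = b""
    while len(buf) < n:
        chunk = sock.recv(n - len(buf))
        if not chunk:
            return None
        buf += chunk
    return buf


def _recv_frame(sock: socket.socket) -> bytes | None:
    head = _recv_exact(sock, _LEN.size)
    if head is None:
        return None
    (length,) = _LEN.unpack(head)
    return _recv_exact(sock, length)


class Broker:
    """Central fan-out point of the bus.

    Publishers stream serialized messages; subscribers declare their topics
    on connect and then receive every matching message, in per-publisher
    order. The broker retains the latest message per topic and replays it to
    late joiners, so selection, camera and play-head state converge no
    matter when a view is launched. Malformed frames are counted and
    skipped.
    """

    def __init__(self, host: str = "127.0.0.1", port: int = 0):
        self._server = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        self._server.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        self._server.bind((host, port))
        self._server.listen()
        self.host, self.port = self._server.getsockname()
        self._lock = threading.Lock()
        self._subs: list[tuple[socket.socket, set[str]]] = []
        self._latest: dict[str, bytes] = {}
        self._running = True
        self.dropped = 0
        self._threads: list[threading.Thread] = []
        self._accept_thread = threading.Thread(target=self._accept_loop, daemon=True)
        self._accept_thread.start()

    @property
    def endpoint(self) -> tuple[str, int]:
        return (self.host, self.port)

    def _accept_loop(self) -> None:
        while self._running:
            try:
                conn, _ = self._server.accept()
            except OSError:
                return
            t = threading.Thread(target=self._serve, args=(conn,), daemon=True)
            t.start()
            self._threads.append(t)

    def _serve(self, conn: socket.socket) -> None:
        try:
            hello = _recv_frame(conn)
            if hello is None:
                conn.close()
                return
            try:
                ctrl = json.loads(hello.decode("utf-8"))
            except (UnicodeDecodeError, json.JSONDecodeError):
                conn.close()
                return
            role = ctrl.get("role")
            if role == "sub":
                topics = {t for t in ctrl.get("topics", []) if t in TOPICS}
                with self._lock:
                    # Replay latest-per-topic state, then go live.
                    for topic in TOPICS:
                        if topic in topics and topic in self._latest:
                            _send_frame(conn, self._latest[topic])
                    self._subs.append((conn, topics))
                return  # connection now owned by the fan-out path
            if role == "pub":
                while True:
                    frame = _recv_frame(conn)
                    if frame is None:
                        break
                    try:
                        msg = deserialize(frame)
                    except BusError:
                        self.dropped += 1
                        continue
                    self._publish(msg.topic, frame)
            conn.close()
        except OSError:
            pass

    def _publish(self, topic: str, frame: bytes) -> None:
        with self._lock:
            self._latest[topic] = frame
            dead = []
            for i, (conn, topics) in enumerate(self._subs):
                if topic not in topics:
                    continue
                try:
                    _send_frame(conn, frame)
                except OSError:
                    dead.append(i)
            for i in reversed(dead):
                self._subs.pop(i)

    def close(self) -> None:
        self._running = False
        try:
            self._server.close()
        except OSError:
            pass
        with self._lock:
            for conn, _ in self._subs:
                try:
                    conn.close()
                except OSError:
                    pass
            self._subs.clear()


class Publisher:
    """Publishes messages to a broker with an automatic monotone seq."""

    def __init__(self, endpoint: tuple[str, int]):
        self._sock = socket.create_connection(endpoint, timeout=5.0)
        _send_frame(self._sock, json.dumps({"role": "pub"}).encode())
        self._seq = 0

    def publish(self, topic: str, payload: dict) -> BusMessage:
        self._seq += 1
        msg = BusMessage(topic=topic, seq=self._seq, payload=payload)
        _send_frame(self._sock, serialize(msg))
        return msg

    def publish_message(self, msg: BusMessage) -> None:
        _send_frame(self._sock, serialize(msg))

    def close(self) -> None:
        try:
            self._sock.close()
        except OSError:
            pass


class Subscriber:
    """Receives messages for a set of topics; late joiners first get the
    broker's retained latest message per topic."""

    def __init__(self, endpoint: tuple[str, int], topics: Iterable[str]):
        self.topics = set(topics)
        unknown = self.topics - set(TOPICS)
        if unknown:
            raise UnknownTopicError(f"unknown topics {sorted(unknown)}")
        self._sock = socket.create_connection(endpoint, timeout=5.0)
        _send_frame(
            self._sock,
            json.dumps({"role": "sub", "topics": sorted(self.topics)}).encode(),
        )

    def receive(self, timeout: float | None = 5.0) -> BusMessage | None:
        """Next message, or None on timeout / closed connection."""
        self._sock.settimeout(timeout)
        try:
            frame = _recv_frame(self._sock)
        except socket.timeout:
            return None
        except OSError:
            return None
        if frame is None:
            return None
        return deserialize(frame)

    def drain(self, timeout: float = 0.2) -> list[BusMessage]:
        """All messages until the line goes quiet for ``timeout`` seconds."""
        out = []
        while True:
            msg = self.receive(timeout=timeout)
            if msg is None:
                return out
            out.append(msg)

    def close(self) -> None:
        try:
            self._sock.close()
        except OSError:
            pass
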