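import logging

# drop per-hit info chatter during large randomized runs
logging.getLogger("crisprpam").setLevel(logging.ERROR)
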