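>synthetic_dnajb6b_standin 241-aa SYNTHETIC stand-in; not the real DNAJB6b sequence; composition matched to reported charge behaviour
NMKGFRRTTTEGDGVTGKKAIGQGPVSFMFGKHREAPMFEAARFFIFECGGPFSFFGTSN
HAHEHHDGSDFFTEGLQNDTGYFRSGGRDGCRTFPRRAKLDKGQLKDMGGVGHSSFVFKD
GVPKFNGGSEGGNHGRFLSGHNGKEFTYFALTESQFHTGTFLDSGNFSFFTDINGFLKEI
ERRAYTHFSFSSFWPKGEFQVHDAFQFFQSFEHAFDSGGYKFGASTFGQSFPPDFKSRLA
M
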